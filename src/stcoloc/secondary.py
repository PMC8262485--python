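"""Suppressed-rank secondary (immune) labeling of spots.

After suppressing the dominant non-immune clusters (epithelium and
endothelium by default), each spot is assigned the top-ranked immune
identity — but only if that immune score strictly exceeds the score of
a fibroblast control. Spots failing the gate, and unassigned spots, are
labeled 'none'. The winner column records which candidate (immune or
control) actually ranked first, which downstream marker discovery uses
to identify fibroblast-colocalized spots.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .deconvolution import ScoreMatrix
from .io import SpotTable

NONE_LABEL = "none"
DEFAULT_CONTROL = "Fibroblast"


def secondary_label(
    scores: ScoreMatrix,
    suppressed: Iterable[str],
    immune: Iterable[str],
    control: str = DEFAULT_CONTROL,
) -> pd.DataFrame:
    """Top-ranked immune label per spot, gated by the control cluster.

    Columns: barcode, label (immune cluster or 'none'), score,
    gate_passed, winner (top non-suppressed candidate among
    immune + control; 'none' for unassigned spots), tie flag.
    Immune-vs-immune ties resolve alphabetically; an immune score that
    only ties the control fails the gate (strict exceedance required).
    """
    suppressed = set(suppressed)
    immune = sorted(set(immune))
    if suppressed & set(immune):
        raise ValueError("suppressed and immune cluster sets overlap")
    if control in suppressed:
        raise ValueError("the control cluster cannot be suppressed")
    if control not in scores.scores.columns:
        raise ValueError(f"control cluster {control!r} absent from the score matrix")
    missing = [c for c in immune if c not in scores.scores.columns]
    if missing:
        raise ValueError(f"immune clusters absent from the score matrix: {missing}")

    rows = []
    ctrl = scores.scores[control]
    imm = scores.scores[immune]
    for barcode in scores.barcodes:
        if not scores.assigned[barcode]:
            rows.append((barcode, NONE_LABEL, 0.0, False, NONE_LABEL, False))
            continue
        imm_row = imm.loc[barcode]
        best_score = float(imm_row.max()) if immune else 0.0
        winners = [c for c in immune if imm_row[c] == best_score] if immune else []
        best_immune = winners[0] if winners else None  # alphabetical tie-break
        tie = len(winners) > 1
        ctrl_score = float(ctrl[barcode])
        if best_immune is not None and best_score > ctrl_score:
            rows.append((barcode, best_immune, best_score, True, best_immune, tie))
        else:
            # gate failed: control ranked at least as high as every immune;
            # a spot with zero mass on all candidates has no winner at all
            winner = control if ctrl_score > 0 else NONE_LABEL
            rows.append((barcode, NONE_LABEL, best_score, False, winner, tie))
    out = pd.DataFrame(
        rows, columns=["barcode", "label", "score", "gate_passed", "winner", "tie"]
    )
    out["coloc_identity"] = np.where(
        out["gate_passed"], out["label"], np.where(out["winner"] == control, control, NONE_LABEL)
    )
    return out


def secondary_label_map(labeling: pd.DataFrame, spots: SpotTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join secondary labels with spot coordinates.

    Returns (display table, full table): the display table omits 'none'
    spots (only the top-ranked immune identity is rendered), the full
    table keeps every spot.
    """
    pos = spots.positions()
    full = labeling.merge(
        pos.reset_index().rename(columns={"obs_id": "barcode"}), on="barcode", how="left"
    )
    display = full[full["label"] != NONE_LABEL].reset_index(drop=True)
    return display, full
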