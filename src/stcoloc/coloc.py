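"""Immune-epithelial colocalization odds ratios with exact inference.

For each (epithelial E, immune I) pair, spots are cross-classified by
dominant label (E vs not) and secondary immune label (I vs not) into a
2x2 table; the association is summarized by the odds ratio ad/(bc), a
one-sided Fisher exact p-value against the null that the odds ratio is
not greater than 1, and a 95% log-scale CI (Haldane-Anscombe corrected
when a cell is empty). Benjamini-Hochberg q-values are attached across
tested pairs but the significance flag mirrors the unadjusted p < 0.05
criterion; both are surfaced.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exact_tests import fisher_exact_greater, fisher_exact_twosided, odds_ratio_ci
from .secondary import NONE_LABEL

ALPHA = 0.05
MIN_SPOTS = 5

COLOC_COLUMNS = [
    "sample",
    "epithelial",
    "immune",
    "a",
    "b",
    "c",
    "d",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "p_value",
    "q_value",
    "significant",
]


def coloc_table(
    dominant: pd.DataFrame,
    secondary: pd.DataFrame,
    sample_id: str,
    epithelial: Iterable[str] | None = None,
    immune: Iterable[str] | None = None,
    min_spots: int = MIN_SPOTS,
    two_sided: bool = False,
) -> pd.DataFrame:
    """One colocalization record per (epithelial, immune) pair.

    ``dominant`` comes from :func:`stcoloc.deconvolution.dominant_labels`
    and ``secondary`` from :func:`stcoloc.secondary.secondary_label`;
    they must cover the same spots. Spots with secondary label 'none'
    count in the not-I margin. Pairs require a+b >= min_spots dominant-E
    spots and at least one I-labeled spot (a+c >= 1).
    """
    dom = dominant.set_index("barcode")["dominant"]
    sec = secondary.set_index("barcode")["label"]
    common = dom.index.intersection(sec.index)
    if len(common) == 0:
        raise ValueError("dominant and secondary labelings cover disjoint spot sets")
    dom = dom.loc[common]
    sec = sec.loc[common]

    if epithelial is None:
        epithelial = sorted(set(dom.unique()) - {NONE_LABEL, "unassigned"})
    if immune is None:
        immune = sorted(set(sec.unique()) - {NONE_LABEL})

    test = fisher_exact_twosided if two_sided else fisher_exact_greater
    rows = []
    for e in sorted(set(epithelial)):
        is_e = (dom == e).to_numpy()
        for i in sorted(set(immune)):
            is_i = (sec == i).to_numpy()
            a = int(np.sum(is_e & is_i))
            b = int(np.sum(is_e & ~is_i))
            c = int(np.sum(~is_e & is_i))
            d = int(np.sum(~is_e & ~is_i))
            if a + b < min_spots or a + c < 1:
                continue
            orr = odds_ratio_ci(a, b, c, d)
            rows.append(
                {
                    "sample": sample_id,
                    "epithelial": e,
                    "immune": i,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": orr.odds_ratio,
                    "ci_low": orr.ci_low,
                    "ci_high": orr.ci_high,
                    "p_value": test(a, b, c, d),
                }
            )
    out = pd.DataFrame(rows, columns=[c for c in COLOC_COLUMNS if c not in ("q_value", "significant")])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_value"] < ALPHA
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out[COLOC_COLUMNS]


def compare_to_reference(
    condition: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair condition and reference colocalization records side by side.

    Returns (paired table, dot-plot export). A pair is flagged
    enriched-in-condition when significant in the condition sample but
    not in the reference (or absent there); the dot-plot export keeps
    only condition-significant pairs.
    """
    cond = condition.rename(
        columns={c: f"{c}_condition" for c in condition.columns if c not in ("epithelial", "immune")}
    )
    ref = reference.drop(columns=["sample"], errors="ignore").rename(
        columns={c: f"{c}_reference" for c in reference.columns if c not in ("epithelial", "immune")}
    )
    paired = cond.merge(ref, on=["epithelial", "immune"], how="left")
    ref_sig = paired.get("significant_reference")
    ref_sig = (
        ref_sig.astype("boolean").fillna(False).astype(bool) if ref_sig is not None else False
    )
    paired["enriched_in_condition"] = paired["significant_condition"].astype(bool) & ~ref_sig
    dot = paired[paired["significant_condition"].astype(bool)][
        [
            "epithelial",
            "immune",
            "odds_ratio_condition",
            "p_value_condition",
            "q_value_condition",
            "enriched_in_condition",
        ]
    ].reset_index(drop=True)
    return paired, dot


def permute_secondary(
    secondary: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute secondary labels across spots (null for colocalization)."""
    out = secondary.copy()
    perm = rng.permutation(len(out))
    for col in ("label", "score", "gate_passed", "winner", "coloc_identity"):
        if col in out.columns:
            out[col] = out[col].to_numpy()[perm]
    return out
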