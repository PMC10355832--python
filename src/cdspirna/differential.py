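"""Condition comparisons: class- and gene-level RPM fold changes with
replicate mean ± SD, cross-condition correlation of gene fold changes, and
degradome enrichment (TPM/TPM)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify_map import LibraryProfile

__all__ = [
    "FoldChangeRecord",
    "class_fold_change",
    "gene_fold_change_matrix",
    "fc_correlation",
    "degradome_enrichment",
    "ratio_with_pseudo",
]

PSEUDO_RPM = 0.5


def ratio_with_pseudo(num: float, den: float, pseudo: float = PSEUDO_RPM,
                      mode: str = "both_if_zero") -> float:
    """Ratio with a small-count guard.

    ``both_if_zero`` adds ``pseudo`` to both terms when either is zero
    (fold-change convention, keeps identical profiles at exactly 1);
    ``zeros_only`` adds it only to zero entries (enrichment convention).
    """
    if mode == "both_if_zero":
        if num == 0 or den == 0:
            num, den = num + pseudo, den + pseudo
    elif mode == "zeros_only":
        num = num if num > 0 else pseudo
        den = den if den > 0 else pseudo
    else:
        raise ValueError(mode)
    return num / den


@dataclass
class FoldChangeRecord:
    unit: str
    case_rpm: list[float]
    control_rpm: list[float]
    fc: list[float]
    fc_mean: float
    fc_sd: float
    pseudo_used: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.fc)


def _fc_record(unit: str, case_vals: Sequence[float],
               control_vals: Sequence[float], pseudo: float) -> FoldChangeRecord:
    fcs, used = [], False
    for c, k in zip(case_vals, control_vals):
        if c == 0 or k == 0:
            used = True
        fcs.append(ratio_with_pseudo(c, k, pseudo))
    arr = np.array(fcs)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return FoldChangeRecord(unit, list(case_vals), list(control_vals), fcs,
                            float(arr.mean()), sd, used)


def _class_rpm(profile: LibraryProfile, cls: str,
               gene_set: Sequence[str] | None) -> float:
    if cls == "genic" and gene_set is not None:
        count = float(profile.genes.loc[list(gene_set), "count"].sum())
        return count * 1e6 / profile.total_after_nonpirna
    return float(profile.class_rpm.get(cls, 0.0))


def class_fold_change(
    case_profiles: Sequence[LibraryProfile],
    control_profiles: Sequence[LibraryProfile],
    classes: Sequence[str] = ("cluster", "TE", "genic"),
    gene_set: Sequence[str] | None = None,
    pseudo: float = PSEUDO_RPM,
) -> dict[str, FoldChangeRecord]:
    """Per-class case/control RPM fold change over explicitly paired
    replicates (case[i] vs control[i]); mean ± SD over pairs.

    The exon-mapper ('genic') class may be restricted to a supplied gene
    set, e.g. the RPM > 10 host tier.
    """
    if len(case_profiles) != len(control_profiles):
        raise ValueError("replicate pairing requires equal-length lists")
    out = {}
    for cls in classes:
        case_vals = [_class_rpm(p, cls, gene_set) for p in case_profiles]
        ctrl_vals = [_class_rpm(p, cls, gene_set) for p in control_profiles]
        out[cls] = _fc_record(cls, case_vals, ctrl_vals, pseudo)
    return out


def gene_fold_change_matrix(
    case_profiles: Sequence[LibraryProfile],
    control_profiles: Sequence[LibraryProfile],
    genes: Sequence[str],
    pseudo: float = PSEUDO_RPM,
) -> tuple[pd.DataFrame, float, float]:
    """Per-gene RPM fold changes for each replicate pair.

    Returns (DataFrame indexed by gene with one fc column per pair plus
    fc_mean/fc_sd, cohort mean across genes, cohort SD across genes).
    """
    if len(case_profiles) != len(control_profiles):
        raise ValueError("replicate pairing requires equal-length lists")
    cols = {}
    for i, (cp, kp) in enumerate(zip(case_profiles, control_profiles), 1):
        fc = []
        for g in genes:
            fc.append(ratio_with_pseudo(float(cp.genes.loc[g, "rpm"]),
                                        float(kp.genes.loc[g, "rpm"]), pseudo))
        cols[f"fc_pair{i}"] = fc
    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    df["fc_mean"] = df.mean(axis=1)
    df["fc_sd"] = df[[c for c in df.columns if c.startswith("fc_pair")]].std(
        axis=1, ddof=1)
    cohort_mean = float(df["fc_mean"].mean())
    cohort_sd = float(df["fc_mean"].std(ddof=1))
    return df, cohort_mean, cohort_sd


def fc_correlation(
    fc_a: Sequence[float], fc_b: Sequence[float], log: bool = True
) -> float:
    """Pearson correlation of matched fold-change vectors (log2 by default).

    Fold changes are ratio-scaled, so the default correlates log2 values;
    zero variance in either vector is undefined (NaN) and flagged by the
    caller.
    """
    a, b = np.asarray(fc_a, float), np.asarray(fc_b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if log:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log-scale correlation requires positive fcs")
        a, b = np.log2(a), np.log2(b)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def degradome_enrichment(
    degradome_tpm: pd.Series,
    polya_tpm: pd.Series,
    genes: Sequence[str] | None = None,
    pseudo: float = PSEUDO_RPM,
) -> pd.DataFrame:
    """Per-gene degradome/poly(A) TPM ratio, ranked descending."""
    genes = list(genes) if genes is not None else sorted(
        set(degradome_tpm.index) & set(polya_tpm.index))
    rows = {
        g: ratio_with_pseudo(float(degradome_tpm.get(g, 0.0)),
                             float(polya_tpm.get(g, 0.0)), pseudo)
        for g in genes
    }
    df = pd.DataFrame({"deg_tpm": degradome_tpm.reindex(genes),
                       "polya_tpm": polya_tpm.reindex(genes),
                       "enrichment": pd.Series(rows)})
    df.index.name = "gene_id"
    return df.sort_values("enrichment", ascending=False)
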