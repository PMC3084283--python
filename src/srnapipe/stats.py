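"""Diversity, sequencing-vs-qPCR agreement, and knockdown statistics.

Three questions from the library comparison are answered here:

* how diverse is a read library within a class of sequences — Shannon's
  H' = -sum p_i ln p_i over read proportions;
* do deep-sequencing read counts quantify expression — Pearson correlation
  between read counts and qPCR abundance, with Student's t significance,
  restricted to sequences with more than 100 reads;
* did a knockdown (e.g. of dicer-1) lower a miRNA — an efficiency-
  corrected expression ratio (Pfaffl style) whose significance comes from
  a pair-wise fixed-reallocation randomization test: group labels of the
  (target, reference) Ct sample pairs are permuted, the pairing within a
  sample never broken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass
class DiversityResult:
    H_prime: float
    S: int
    proportions: np.ndarray


def shannon_index(counts) -> DiversityResult:
    """Shannon diversity H' (natural log) over positive counts."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0 or np.all(arr == 0):
        raise ValueError("shannon_index needs at least one positive count")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    arr = arr[arr > 0]
    p = arr / arr.sum()
    return DiversityResult(H_prime=float(sps.entropy(p)), S=int(arr.size), proportions=p)


@dataclass(frozen=True)
class AbundancePair:
    name: str
    reads: float
    qpcr: float  # copies per 1000 copies of the reference gene


def correlate_reads_qpcr(
    pairs: list[AbundancePair], min_reads: int = 101
) -> tuple[float, float, int]:
    """Pearson R between read counts and qPCR abundance, after the read filter.

    ``min_reads`` = 101 encodes the strict "more than 100 reads" rule.
    Significance is the two-sided Student's t on R with n-2 df. Fewer than
    3 surviving pairs, or zero variance, is an error.
    """
    kept = [p for p in pairs if p.reads >= min_reads]
    if len(kept) < 3:
        raise ValueError(f"need >= 3 pairs after the read filter, have {len(kept)}")
    x = np.array([p.reads for p in kept], dtype=float)
    y = np.array([p.qpcr for p in kept], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in reads or qPCR values")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(kept)


@dataclass
class QPCRMeasurement:
    """Ct replicates for one gene in both groups, with amplification efficiency."""

    gene: str
    control: list[float]
    treated: list[float]
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError(f"efficiency {self.efficiency} outside (1, 2]")
        if len(self.control) < 2 or len(self.treated) < 2:
            raise ValueError(f"gene {self.gene!r}: >= 2 Ct replicates per group required")
        if any(ct <= 0 for ct in self.control + self.treated):
            raise ValueError(f"gene {self.gene!r}: Ct values must be positive")


@dataclass
class ExpressionTest:
    ratio: float
    p_value: float
    n_randomizations: int
    seed: int | None
    exhaustive: bool


def _pfaffl_ratio(et: float, er: float, d_target: float, d_ref: float) -> float:
    return et**d_target / er**d_ref


def rest_ratio_test(
    target: QPCRMeasurement,
    reference: QPCRMeasurement,
    n_randomizations: int = 10_000,
    seed: int | None = None,
) -> ExpressionTest:
    """Efficiency-corrected relative expression with a randomization p-value.

    ratio = E_t^(mean Ct_t,ctrl - mean Ct_t,trt) / E_r^(mean Ct_r,ctrl - mean Ct_r,trt).

    Significance: group labels of whole samples (a sample = one paired
    target/reference Ct observation) are reallocated; p is the fraction of
    reallocations with |log ratio| >= the observed one. All C(n, n_ctrl)
    reallocations are enumerated when that is <= ``n_randomizations``,
    otherwise that many are sampled with the given seed (observed labelling
    counted in).
    """
    if len(target.control) != len(reference.control) or len(target.treated) != len(
        reference.treated
    ):
        raise ValueError("target and reference must share the sample structure per group")
    tc, tt = np.array(target.control), np.array(target.treated)
    rc, rt = np.array(reference.control), np.array(reference.treated)
    ratio = _pfaffl_ratio(
        target.efficiency, reference.efficiency, tc.mean() - tt.mean(), rc.mean() - rt.mean()
    )
    n_c = len(tc)
    n = n_c + len(tt)
    t_all = np.concatenate([tc, tt])
    r_all = np.concatenate([rc, rt])
    log_et, log_er = math.log(target.efficiency), math.log(reference.efficiency)
    observed = abs(log_et * (tc.mean() - tt.mean()) - log_er * (rc.mean() - rt.mean()))

    def log_ratio(ctrl_idx: np.ndarray) -> np.ndarray:
        mask = np.zeros((ctrl_idx.shape[0], n), dtype=bool)
        np.put_along_axis(mask, ctrl_idx, True, axis=1)
        tm_c = (t_all * mask).sum(axis=1) / n_c
        tm_t = (t_all * ~mask).sum(axis=1) / (n - n_c)
        rm_c = (r_all * mask).sum(axis=1) / n_c
        rm_t = (r_all * ~mask).sum(axis=1) / (n - n_c)
        return log_et * (tm_c - tm_t) - log_er * (rm_c - rm_t)

    n_exhaustive = math.comb(n, n_c)
    if n_exhaustive <= n_randomizations:
        idx = np.array(list(combinations(range(n), n_c)), dtype=int)
        lr = log_ratio(idx)
        p = float(np.mean(np.abs(lr) >= observed - 1e-12))
        return ExpressionTest(ratio, p, n_exhaustive, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    idx = np.array(
        [rng.choice(n, size=n_c, replace=False) for _ in range(n_randomizations)], dtype=int
    )
    lr = log_ratio(idx)
    extreme = int(np.sum(np.abs(lr) >= observed - 1e-12))
    p = (1 + extreme) / (1 + n_randomizations)
    return ExpressionTest(ratio, float(p), n_randomizations, seed, exhaustive=False)


# ---------------------------------------------------------------------------
# library composition (the two-library comparison)

COMPOSITION_CLASSES = (
    "known_miRNA",
    "miRNA_star",
    "conserved_candidate",
    "specific_candidate",
    "other_small_RNAs",
    "unassigned",
)

_STATUS_TO_CLASS = {
    "known": "known_miRNA",
    "star": "miRNA_star",
    "conserved_candidate": "conserved_candidate",
    "specific_candidate": "specific_candidate",
    "contaminant": "other_small_RNAs",
    "artefact": "unassigned",
    "unassigned": "unassigned",
}

#: classes whose within-class read diversity is reported
DIVERSITY_CLASSES = ("known_miRNA", "conserved_candidate", "specific_candidate")


def compare_libraries(rows, libraries: list[str]):
    """Per-library composition fractions and per-class Shannon diversity.

    ``rows`` are candidate-table rows (status + per-library counts). Returns
    (composition, diversity) DataFrames; composition fractions sum to 1 per
    library. "Other small RNAs" pools the structural/foreign categories.
    """
    import pandas as pd

    if len(libraries) < 2:
        raise ValueError("compare_libraries needs >= 2 libraries")
    comp = {lib: {cls: 0 for cls in COMPOSITION_CLASSES} for lib in libraries}
    per_class_counts: dict[tuple[str, str], list[int]] = {}
    for row in rows:
        base = row.status.split(":", 1)[0]
        if base not in _STATUS_TO_CLASS:
            raise ValueError(f"unknown status {row.status!r}")
        cls = _STATUS_TO_CLASS[base]
        for lib in libraries:
            n = row.counts.get(lib, 0)
            comp[lib][cls] += n
            if n > 0 and cls in DIVERSITY_CLASSES:
                per_class_counts.setdefault((lib, cls), []).append(n)
    comp_rows = []
    for lib in libraries:
        total = sum(comp[lib].values())
        if total == 0:
            raise ValueError(f"library {lib!r} has no reads")
        for cls in COMPOSITION_CLASSES:
            comp_rows.append(
                {"library": lib, "class": cls, "reads": comp[lib][cls],
                 "fraction": comp[lib][cls] / total}
            )
    div_rows = []
    for lib in libraries:
        for cls in DIVERSITY_CLASSES:
            counts = per_class_counts.get((lib, cls), [])
            h = shannon_index(counts).H_prime if counts else float("nan")
            div_rows.append({"library": lib, "class": cls, "S": len(counts), "H_prime": h})
    return pd.DataFrame(comp_rows), pd.DataFrame(div_rows)


def qpcr_abundance_from_ct(
    gene_ct: float, reference_ct: float, efficiency: float = 2.0, per: float = 1000.0
) -> float:
    """Copies of a gene per ``per`` copies of the reference, from mean Cts."""
    return per * efficiency ** (reference_ct - gene_ct)
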