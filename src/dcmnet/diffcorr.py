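"""Differential correlation statistics for paired two-compartment metabolomics.

For every unordered metabolite pair (i, j) the change in the Pearson
correlation between plasma and joint fluid is scored by the Fisher
z-based statistic

    r_diff(i, j) = sqrt((n_plasma - 3) / 2) * z_plasma(i, j)
                 - sqrt((n_JF - 3) / 2) * z_JF(i, j)

where z = arctanh(r) is the Fisher z-transformation. When the two sample
sizes are equal this reduces exactly to the textbook normal-deviate test for
the equality of two correlations, (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)).

Significance is assessed by permutation of the compartment labels: one
shared set of label shufflings is applied to all pairs, the full r_diff
vector is recomputed per shuffle, and two-sided p-values use the add-one
correction p = (1 + #{|perm| >= |obs|}) / (B + 1), which is never zero and
controls type-I error. Multiple testing across the m(m-1)/2 pairs is handled
by Bonferroni (default) or Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel_io import PairedDataset

logger = logging.getLogger(__name__)

#: |r| is clamped below this before the z-transform to avoid infinities from
#: degenerate (perfectly collinear) columns.
R_CLAMP = 1.0 - 1e-7

PERMUTATION_SCHEMES = ("pooled", "paired")
CORRECTION_METHODS = ("bonferroni", "bh", "none")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over an ordered metabolite list."""

    metabolite_ids: list[str]
    r: np.ndarray
    n: int

    def __post_init__(self) -> None:
        m = len(self.metabolite_ids)
        if self.r.shape != (m, m):
            raise ValueError("correlation matrix shape does not match id list")


@dataclass
class DiffCorrResult:
    """Per-pair differential correlation records plus run metadata.

    ``table`` has one row per unordered metabolite pair with columns
    metabolite_i, metabolite_j, r_plasma, r_jf, z_plasma, z_jf, r_diff and,
    once permutation testing has run, p_perm / sig_nominal / sig_adjusted.
    """

    table: pd.DataFrame
    n_plasma: int
    n_jf: int
    stratum: str = ""
    permutations: int = 0
    alpha: float | None = None
    correction: str | None = None
    adjusted_threshold: float | None = None
    scheme: str | None = None
    seed: int | None = None
    weighted: bool = True

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def significant(self, tier: str = "nominal") -> pd.DataFrame:
        col = {"nominal": "sig_nominal", "adjusted": "sig_adjusted"}.get(tier)
        if col is None:
            raise ValueError(f"unknown tier {tier!r}; use 'nominal' or 'adjusted'")
        if col not in self.table:
            raise ValueError(f"{col} not computed yet")
        return self.table[self.table[col]]


def pearson_matrix(data: pd.DataFrame | np.ndarray,
                   metabolite_ids: Sequence[str] | None = None) -> CorrelationMatrix:
    """Product-moment correlation of a complete samples x metabolites matrix."""
    if isinstance(data, pd.DataFrame):
        metabolite_ids = list(data.columns)
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        if metabolite_ids is None:
            metabolite_ids = [f"M{k}" for k in range(values.shape[1])]
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; impute first")
    n = values.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = [metabolite_ids[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance metabolites: {bad}")
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(metabolite_ids), r, n)


def fisher_z(r):
    """Fisher z-transformation, z = arctanh(r) = 0.5*ln((1+r)/(1-r)).

    Correlations at +/-1 (degenerate, perfectly collinear inputs) are
    clamped to +/-(1 - 1e-7) so the transform stays finite.
    """
    r = np.asarray(r, dtype=float)
    if np.isnan(r).any():
        raise ValueError("NaN correlation passed to fisher_z")
    out = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    return out if out.ndim else float(out)


def r_diff(r_plasma, r_jf, n_plasma: int, n_jf: int, weighted: bool = True):
    """Differential correlation statistic between plasma and joint fluid.

    Subtracts the joint-fluid term from the plasma term, each Fisher
    z-transformed and weighted by sqrt((n - 3) / 2). With ``weighted=False``
    the raw z-difference is returned (sensitivity analysis only).
    """
    if n_plasma <= 3 or n_jf <= 3:
        raise ValueError(
            f"sample sizes must exceed 3 (variance term n - 3); "
            f"got n_plasma={n_plasma}, n_jf={n_jf}"
        )
    zp = fisher_z(r_plasma)
    zj = fisher_z(r_jf)
    if not weighted:
        return zp - zj
    return np.sqrt((n_plasma - 3) / 2.0) * zp - np.sqrt((n_jf - 3) / 2.0) * zj


def _pair_index(m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(m, k=1)


def diffcorr_all_pairs(paired: PairedDataset, weighted: bool = True) -> DiffCorrResult:
    """r_diff for every unordered metabolite pair of a paired dataset."""
    cp = pearson_matrix(paired.plasma)
    cj = pearson_matrix(paired.jf)
    iu, ju = _pair_index(len(cp.metabolite_ids))
    rp = cp.r[iu, ju]
    rj = cj.r[iu, ju]
    ids = np.asarray(cp.metabolite_ids)
    table = pd.DataFrame(
        {
            "metabolite_i": ids[iu],
            "metabolite_j": ids[ju],
            "r_plasma": rp,
            "r_jf": rj,
            "z_plasma": fisher_z(rp),
            "z_jf": fisher_z(rj),
            "r_diff": r_diff(rp, rj, cp.n, cj.n, weighted=weighted),
        }
    )
    return DiffCorrResult(
        table=table, n_plasma=cp.n, n_jf=cj.n,
        stratum=paired.stratum, weighted=weighted,
    )


def _rdiff_vector(values: np.ndarray, n1: int, weighted: bool) -> np.ndarray:
    """r_diff over all pairs for a stacked (group1 above group2) matrix."""
    g1, g2 = values[:n1], values[n1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.corrcoef(g1, rowvar=False)
        r2 = np.corrcoef(g2, rowvar=False)
    # a permuted group can be constant by chance on ties; score those pairs 0
    r1 = np.nan_to_num(r1)
    r2 = np.nan_to_num(r2)
    iu, ju = _pair_index(values.shape[1])
    return r_diff(r1[iu, ju], r2[iu, ju], g1.shape[0], g2.shape[0], weighted=weighted)


def permutation_pvalues(
    paired: PairedDataset,
    B: int = 1000,
    scheme: str = "pooled",
    seed: int = 0,
    alpha: float = 0.05,
    weighted: bool = True,
) -> DiffCorrResult:
    """Permutation p-values for the differential correlation of every pair.

    One shared set of B compartment-label shufflings is applied to all pairs
    (the standard global-null construction). ``scheme="pooled"`` re-assigns
    all samples at random to two groups of the original sizes;
    ``scheme="paired"`` swaps the plasma/JF labels independently within each
    subject, which requires every subject to contribute both compartments.
    Two-sided p-values use the add-one correction, so p is in
    [1/(B+1), 1]; ties in |r_diff| count as exceedances (conservative).
    """
    if B < 1:
        raise ValueError(f"permutation count B must be >= 1, got {B}")
    if scheme not in PERMUTATION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; use one of {PERMUTATION_SCHEMES}")
    result = diffcorr_all_pairs(paired, weighted=weighted)
    obs = np.abs(result.table["r_diff"].to_numpy())
    n1, n2 = result.n_plasma, result.n_jf

    values = np.vstack(
        [paired.plasma.to_numpy(dtype=float), paired.jf.to_numpy(dtype=float)]
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs), dtype=np.int64)

    if scheme == "paired":
        plasma_by_subject = dict(zip(paired.plasma_subjects, range(n1)))
        jf_by_subject = dict(zip(paired.jf_subjects, range(n2)))
        incomplete = sorted(
            set(plasma_by_subject) ^ set(jf_by_subject)
        )
        if incomplete:
            raise ValueError(
                "paired scheme needs both compartments per subject; "
                f"offending subjects: {incomplete}"
            )
        subjects = sorted(plasma_by_subject)
        p_rows = np.array([plasma_by_subject[s] for s in subjects])
        j_rows = np.array([jf_by_subject[s] for s in subjects]) + n1
        for _ in range(B):
            swap = rng.random(len(subjects)) < 0.5
            order = np.arange(values.shape[0])
            order[p_rows[swap]], order[j_rows[swap]] = (
                j_rows[swap], p_rows[swap],
            )
            exceed += _rdiff_vector(values[order], n1, weighted) ** 2 >= obs**2
    else:
        for _ in range(B):
            order = rng.permutation(values.shape[0])
            exceed += _rdiff_vector(values[order], n1, weighted) ** 2 >= obs**2

    p = (1.0 + exceed) / (B + 1.0)
    result.table["p_perm"] = p
    result.table["sig_nominal"] = p < alpha
    result.permutations = B
    result.alpha = alpha
    result.scheme = scheme
    result.seed = seed
    return result


def analytic_pvalues(result: DiffCorrResult) -> np.ndarray:
    """Normal-approximation two-sided p-values (cross-check only).

    Valid only for the sqrt((n-3)/2)-weighted statistic, whose null
    distribution is approximately standard normal.
    """
    if not result.weighted:
        raise ValueError("analytic p-values require the weighted statistic")
    return 2.0 * stats.norm.sf(np.abs(result.table["r_diff"].to_numpy()))


def adjust_significance(
    result: DiffCorrResult, alpha: float = 0.05, method: str = "bonferroni"
) -> DiffCorrResult:
    """Flag pairs that stay significant after multiple-testing correction.

    Bonferroni flags p < alpha / m_pairs; "bh" applies the
    Benjamini-Hochberg step-up procedure at level alpha; "none" copies the
    nominal flags. When the permutation floor 1/(B+1) exceeds the Bonferroni
    threshold no pair can survive and a warning is emitted.
    """
    if method not in CORRECTION_METHODS:
        raise ValueError(f"unknown method {method!r}; use one of {CORRECTION_METHODS}")
    if "p_perm" not in result.table:
        raise ValueError("p-values not computed yet; run permutation_pvalues first")
    p = result.table["p_perm"].to_numpy()
    m = len(p)
    if method == "bonferroni":
        threshold = alpha / m
        flags = p < threshold
        if result.permutations and 1.0 / (result.permutations + 1) > threshold:
            warnings.warn(
                f"permutation floor 1/(B+1) = {1.0 / (result.permutations + 1):.2e} "
                f"exceeds the Bonferroni threshold {threshold:.2e}; no pair can be "
                "adjusted-significant at this B — increase the permutation count "
                "or use analytic p-values as a cross-check",
                UserWarning,
                stacklevel=2,
            )
    elif method == "bh":
        flags, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")[0:4]
        threshold = alpha
    else:
        threshold = alpha
        flags = p < alpha
    result.table["sig_adjusted"] = flags
    result.correction = method
    result.adjusted_threshold = float(threshold)
    return result


def bonferroni_threshold(alpha: float, m_pairs: int) -> float:
    """Familywise threshold alpha / m_pairs (e.g. 0.05 / 13861 = 3.6e-6)."""
    if m_pairs < 1:
        raise ValueError("m_pairs must be positive")
    return alpha / m_pairs


def write_diffcorr_table(result: DiffCorrResult, path: str | Path) -> None:
    """Serialize a DiffCorrResult: '#'-prefixed metadata header, then TSV."""
    path = Path(path)
    meta = {
        "stratum": result.stratum,
        "n_plasma": result.n_plasma,
        "n_jf": result.n_jf,
        "permutations": result.permutations,
        "alpha": result.alpha,
        "correction": result.correction,
        "adjusted_threshold": result.adjusted_threshold,
        "scheme": result.scheme,
        "seed": result.seed,
        "weighted": result.weighted,
    }
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        result.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_diffcorr_table(path: str | Path) -> DiffCorrResult:
    """Read a table written by :func:`write_diffcorr_table`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
        table = pd.read_csv(fh, sep="\t")

    def opt(key, cast):
        v = meta.get(key)
        return None if v in (None, "None", "") else cast(v)

    return DiffCorrResult(
        table=table,
        n_plasma=int(meta["n_plasma"]),
        n_jf=int(meta["n_jf"]),
        stratum=meta.get("stratum", ""),
        permutations=opt("permutations", int) or 0,
        alpha=opt("alpha", float),
        correction=opt("correction", str),
        adjusted_threshold=opt("adjusted_threshold", float),
        scheme=opt("scheme", str),
        seed=opt("seed", int),
        weighted=meta.get("weighted", "True") == "True",
    )
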