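"""Synthetic paired two-compartment metabolomics cohorts with known ground truth.

Emulates a targeted-panel study in which every subject contributes one
plasma and one joint-fluid (JF) sample: latent multivariate normal vectors
are drawn per subject per compartment with compartment-specific correlation
matrices that share a dominant positive within-class backbone and differ
exactly at a small set of planted differentially correlated pairs. Latent
values are exponentiated to lognormal concentrations (positivity and right
skew, as in real targeted assays) and left-censored below a per-metabolite
quantile to mimic below-LOD dropout. A configurable number of metabolites is
planted with high missingness so the detection filter has something to drop.

Planted differential-pair members are detached from their class backbone
(their within-class correlations are zeroed), which keeps both target
matrices positive semi-definite by construction; arbitrary user-supplied
targets are repaired by nearest-PSD projection when needed.

Correlation targets are set on the latent Gaussian scale; observed-scale
Pearson correlations of the lognormal concentrations are attenuated, so
recovery is assessed by ranks and calibrated nulls rather than exact r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import CohortDesign, ConcentrationTable

#: class composition of the default 186-metabolite targeted panel
DEFAULT_PANEL: dict[str, int] = {
    "glycerophospholipid": 90,
    "acylcarnitine": 40,
    "amino acid": 21,
    "biogenic amine": 19,
    "sphingolipid": 15,
    "hexose": 1,
}

_CLASS_PREFIX = {
    "glycerophospholipid": "PC",
    "acylcarnitine": "AC",
    "amino acid": "AA",
    "biogenic amine": "BA",
    "sphingolipid": "SM",
    "hexose": "HEX",
    "other": "X",
}

#: demographic distributions per stratum: (age mean, age sd, bmi mean, bmi sd)
_DEMOGRAPHICS = {
    "female": (65.6, 7.1, 33.4, 6.3),
    "male": (64.4, 8.1, 31.7, 5.3),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    Defaults describe the emulated study: 50 subjects per sex stratum, each
    sampled in plasma and joint fluid; a 186-metabolite panel of which 19 are
    planted below the 80% detection threshold (167 retained); a latent
    within-class correlation backbone of 0.5; 10 planted differential pairs
    with latent r 0.7 in plasma vs 0.1 in JF; 5% below-LOD missingness on
    well-detected metabolites and a lognormal coefficient of variation of
    about 50% (log-scale SD 0.5).
    """

    n_subjects: int = 50
    strata: tuple[str, ...] = ("female", "male")
    panel: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PANEL))
    backbone_r: float = 0.5
    n_differential_pairs: int = 10
    diff_r_plasma: float = 0.7
    diff_r_jf: float = 0.1
    differential_pairs: tuple[tuple[str, str, float, float], ...] | None = None
    lod_missing_rate: float = 0.05
    low_detection_metabolites: int = 19
    low_detection_rate: float = 0.30
    log_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in (("backbone_r", self.backbone_r),
                        ("diff_r_plasma", self.diff_r_plasma),
                        ("diff_r_jf", self.diff_r_jf)):
            if not -1 < r < 1:
                raise ValueError(f"{name} must be in (-1, 1), got {r}")
        if not 0 <= self.lod_missing_rate < 1:
            raise ValueError("lod_missing_rate must be in [0, 1)")
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects per stratum")
        total = sum(self.panel.values())
        usable = total - self.low_detection_metabolites
        if self.n_differential_pairs * 2 > usable:
            raise ValueError("too many differential pairs for the panel size")

    @property
    def n_metabolites(self) -> int:
        return sum(self.panel.values())


def panel_metabolites(panel: Mapping[str, int]) -> tuple[list[str], dict[str, str]]:
    """Deterministic metabolite ids and their class map for a panel spec."""
    ids: list[str] = []
    classes: dict[str, str] = {}
    for cls, count in panel.items():
        prefix = _CLASS_PREFIX.get(cls, "M")
        for k in range(count):
            mid = f"{prefix}{k + 1:03d}"
            ids.append(mid)
            classes[mid] = cls
    return ids, classes


def nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Nearest positive semi-definite correlation matrix (eigenvalue clipping).

    Negative eigenvalues are clipped at zero, the matrix is reassembled and
    rescaled back to unit diagonal. PSD inputs are returned unchanged.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("nearest_psd requires a symmetric matrix")
    vals, vecs = np.linalg.eigh(m)
    if vals[0] >= 0:
        return m.copy()
    vals = np.clip(vals, 0.0, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def _target_matrices(
    spec: SyntheticSpec,
    ids: Sequence[str],
    classes: Mapping[str, str],
    pairs: Sequence[tuple[str, str, float, float]],
    max_psd_distance: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent correlation targets for (plasma, JF)."""
    index = {mid: k for k, mid in enumerate(ids)}
    m = len(ids)
    base = np.zeros((m, m))
    for cls in set(classes.values()):
        members = [index[mid] for mid in ids if classes[mid] == cls]
        ix = np.ix_(members, members)
        base[ix] = spec.backbone_r
    np.fill_diagonal(base, 1.0)
    # planted-pair members leave the class backbone so both targets stay PSD
    planted = {index[i] for i, j, *_ in pairs} | {index[j] for _, j, *_ in pairs}
    for k in planted:
        base[k, :] = 0.0
        base[:, k] = 0.0
        base[k, k] = 1.0
    r_plasma = base.copy()
    r_jf = base.copy()
    for i, j, rp, rj in pairs:
        a, b = index[i], index[j]
        r_plasma[a, b] = r_plasma[b, a] = rp
        r_jf[a, b] = r_jf[b, a] = rj
    out = []
    for target in (r_plasma, r_jf):
        repaired = nearest_psd(target)
        dist = float(np.max(np.abs(repaired - target)))
        if dist > max_psd_distance:
            raise ValueError(
                f"correlation targets are far from PSD (projection moved an entry "
                f"by {dist:.3f}); request milder targets"
            )
        out.append(repaired)
    return out[0], out[1]


def _default_pairs(
    spec: SyntheticSpec, ids: Sequence[str], low_detection: set[str]
) -> tuple[tuple[str, str, float, float], ...]:
    """Disjoint cross-panel pairs over well-detected metabolites."""
    usable = [mid for mid in ids if mid not in low_detection]
    half = len(usable) // 2
    pairs = []
    for t in range(spec.n_differential_pairs):
        pairs.append(
            (usable[t], usable[half + t], spec.diff_r_plasma, spec.diff_r_jf)
        )
    return tuple(pairs)


def _censor_lowest(values: np.ndarray, rate: float) -> np.ndarray:
    """Set the lowest round(n*rate) entries of each column to NaN (below LOD)."""
    out = values.copy()
    n = out.shape[0]
    k = int(round(n * rate))
    if k == 0:
        return out
    order = np.argsort(out, axis=0)
    for col in range(out.shape[1]):
        out[order[:k, col], col] = np.nan
    return out


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[ConcentrationTable, CohortDesign, list[tuple[str, str, float, float]]]:
    """Generate a paired cohort: concentrations, metadata and ground truth.

    Returns the full concentration table (all strata and compartments
    stacked), the matching cohort design, and the list of planted
    differential pairs as (metabolite_i, metabolite_j, r_plasma, r_jf) on the
    latent scale. Identical specs (including the seed) give bit-identical
    cohorts; the generator never touches global random state.
    """
    rng = np.random.default_rng(spec.seed)
    ids, classes = panel_metabolites(spec.panel)
    m = len(ids)

    # low-detection metabolites: evenly spread over the panel
    if spec.low_detection_metabolites:
        step = max(1, m // spec.low_detection_metabolites)
        low_idx = [(k * step) % m for k in range(spec.low_detection_metabolites)]
        low_idx = sorted(set(low_idx))
        while len(low_idx) < spec.low_detection_metabolites:
            extra = next(k for k in range(m) if k not in set(low_idx))
            low_idx.append(extra)
            low_idx.sort()
        low_detection = {ids[k] for k in low_idx}
    else:
        low_detection = set()

    pairs = spec.differential_pairs
    if pairs is None:
        pairs = _default_pairs(spec, ids, low_detection)
    for i, j, rp, rj in pairs:
        if i not in classes or j not in classes:
            raise ValueError(f"differential pair ({i}, {j}) not in the panel")
        for name, r in (("r_plasma", rp), ("r_jf", rj)):
            if not -1 < r < 1:
                raise ValueError(f"pair ({i}, {j}) {name}={r} outside (-1, 1)")

    r_plasma, r_jf = _target_matrices(spec, ids, classes, pairs)
    jitter = 1e-10 * np.eye(m)
    chol = {
        "plasma": np.linalg.cholesky(r_plasma + jitter),
        "JF": np.linalg.cholesky(r_jf + jitter),
    }
    # per-metabolite log-mean concentrations, shared across compartments
    mu_log = rng.uniform(np.log(0.5), np.log(100.0), size=m)

    frames: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    for stratum in spec.strata:
        age_mu, age_sd, bmi_mu, bmi_sd = _DEMOGRAPHICS.get(
            stratum, (65.0, 7.6, 32.6, 5.8)
        )
        prefix = stratum[:1].upper()
        subjects = [f"{prefix}{k + 1:03d}" for k in range(spec.n_subjects)]
        ages = rng.normal(age_mu, age_sd, size=spec.n_subjects)
        bmis = rng.normal(bmi_mu, bmi_sd, size=spec.n_subjects)
        for comp in ("plasma", "JF"):
            z = rng.standard_normal((spec.n_subjects, m))
            latent = mu_log + spec.log_sigma * (z @ chol[comp].T)
            conc = np.exp(latent)
            # left-censor below-LOD values, per metabolite, within this block
            rates = np.array(
                [
                    spec.low_detection_rate if mid in low_detection
                    else spec.lod_missing_rate
                    for mid in ids
                ]
            )
            censored = conc.copy()
            n = censored.shape[0]
            order = np.argsort(censored, axis=0)
            for col in range(m):
                k = int(round(n * rates[col]))
                if k:
                    censored[order[:k, col], col] = np.nan
            sample_ids = [f"{s}_{comp}" for s in subjects]
            frames.append(pd.DataFrame(censored, index=sample_ids, columns=ids))
            for s, sid, age, bmi in zip(subjects, sample_ids, ages, bmis):
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": s,
                        "compartment": comp,
                        "stratum": stratum,
                        "age": round(float(age), 1),
                        "bmi": round(float(bmi), 1),
                    }
                )

    data = pd.concat(frames, axis=0)
    data.index.name = "sample_id"
    table = ConcentrationTable(data, classes)
    design = CohortDesign(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, design, [tuple(p) for p in pairs]


def write_cohort(
    table: ConcentrationTable,
    design: CohortDesign,
    ground_truth: Sequence[tuple[str, str, float, float]],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a cohort in the delimited formats the reader expects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "concentrations": outdir / "concentrations.csv",
        "metadata": outdir / "metadata.csv",
        "classes": outdir / "classes.csv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    table.data.to_csv(paths["concentrations"], na_rep="NA", lineterminator="\n")
    meta = design.table.reset_index()
    meta.to_csv(paths["metadata"], index=False, lineterminator="\n")
    cls = pd.DataFrame(
        {"metabolite_id": list(table.classes or {}),
         "class": list((table.classes or {}).values())}
    )
    cls.to_csv(paths["classes"], index=False, lineterminator="\n")
    gt = pd.DataFrame(
        ground_truth,
        columns=["metabolite_i", "metabolite_j", "r_plasma", "r_jf"],
    )
    gt.to_csv(paths["ground_truth"], sep="\t", index=False, lineterminator="\n")
    return paths
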