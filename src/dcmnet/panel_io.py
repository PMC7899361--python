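"""Reading, validation and preprocessing of targeted metabolomics panels.

Handles wide-format concentration tables (samples x metabolites) as exported
by targeted assays such as the Biocrates AbsoluteIDQ p180, together with a
sample metadata table binding each sample to a subject, a compartment
(plasma or joint fluid) and a sex stratum.

Preprocessing follows the common targeted-panel recipe: a metabolite is
retained only if it was detected in strictly more than ``min_fraction`` of
the samples, and remaining below-detection (missing) values are imputed with
half the smallest observed concentration of that metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

COMPARTMENTS = ("plasma", "JF")

#: metabolite classes of the 186-analyte targeted panel
PANEL_CLASSES = (
    "glycerophospholipid",
    "acylcarnitine",
    "amino acid",
    "biogenic amine",
    "sphingolipid",
    "hexose",
    "other",
)

METADATA_COLUMNS = ("sample_id", "subject_id", "compartment", "stratum", "age", "bmi")


class PanelValidationError(ValueError):
    """Raised when a concentration table or metadata table is malformed."""


@dataclass
class ConcentrationTable:
    """Samples x metabolites concentration matrix with explicit missingness.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with one column per metabolite.
        Missing (below detection) entries are ``NaN``.
    classes:
        Optional map from metabolite id to its panel class.
    """

    data: pd.DataFrame
    classes: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise PanelValidationError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise PanelValidationError(f"duplicate metabolite ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            bad = self.data.columns[(self.data < 0).any(axis=0)].tolist()
            raise PanelValidationError(
                f"negative concentrations in metabolites: {bad}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    def detection_fraction(self) -> pd.Series:
        """Fraction of samples in which each metabolite was detected."""
        return self.data.notna().mean(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ConcentrationTable":
        return ConcentrationTable(self.data.loc[list(sample_ids)], self.classes)


@dataclass
class CohortDesign:
    """Sample metadata: subject, compartment, stratum, age and BMI per sample."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        required = {"subject_id", "compartment", "stratum"}
        missing = required - set(self.table.columns)
        if missing:
            raise PanelValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise PanelValidationError(f"duplicate sample ids in metadata: {dups}")
        bad = set(self.table["compartment"].unique()) - set(COMPARTMENTS)
        if bad:
            raise PanelValidationError(
                f"unknown compartments {sorted(bad)}; expected one of {COMPARTMENTS}"
            )
        # a subject contributes at most one sample per compartment
        counts = self.table.groupby(["subject_id", "compartment"]).size()
        repeats = counts[counts > 1]
        if len(repeats):
            raise PanelValidationError(
                "subjects with more than one sample in a compartment: "
                f"{sorted({s for s, _ in repeats.index})}"
            )

    @property
    def strata(self) -> list[str]:
        return sorted(self.table["stratum"].unique())

    def samples_of(self, stratum: str, compartment: str | None = None) -> list[str]:
        mask = self.table["stratum"] == stratum
        if compartment is not None:
            mask &= self.table["compartment"] == compartment
        return list(self.table.index[mask])


@dataclass
class PairedDataset:
    """A stratum's plasma and joint-fluid concentration matrices, aligned.

    Both matrices carry the same metabolite list in the same order and are
    complete (no missing values) after preprocessing. Sample counts must
    exceed 3 on each side so that the Fisher variance terms n - 3 of the
    differential correlation statistic are positive.
    """

    stratum: str
    plasma: pd.DataFrame  # samples x metabolites, complete
    jf: pd.DataFrame
    plasma_subjects: list = field(default_factory=list)
    jf_subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.plasma.columns) != list(self.jf.columns):
            raise PanelValidationError(
                "plasma and JF tables carry different metabolite lists"
            )
        for name, df in (("plasma", self.plasma), ("JF", self.jf)):
            if df.shape[0] < 4:
                raise PanelValidationError(
                    f"compartment {name!r} has {df.shape[0]} samples; at least 4 "
                    "are required (the Fisher variance term n - 3 must be positive)"
                )
            if df.isna().any().any():
                raise PanelValidationError(
                    f"compartment {name!r} still contains missing values; "
                    "run the detection filter and imputation first"
                )

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.plasma.columns)

    @property
    def n_plasma(self) -> int:
        return self.plasma.shape[0]

    @property
    def n_jf(self) -> int:
        return self.jf.shape[0]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_concentration_table(
    path: str | Path,
    missing_tokens: Iterable[str] = ("", "NA", "<LOD"),
    zero_as_missing: bool = False,
    class_path: str | Path | None = None,
) -> ConcentrationTable:
    """Read a wide-format concentration table from delimited text.

    The first column holds sample ids; the header row holds metabolite ids.
    Cells matching ``missing_tokens`` become explicit missing values. With
    ``zero_as_missing`` a literal 0 is treated as below detection, for
    assays that encode <LOD that way.
    """
    raw = _read_delimited(path)
    tokens = set(missing_tokens)
    if zero_as_missing:
        tokens |= {"0", "0.0"}
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "sample_id"

    def convert(cell: str, row: str, col: str) -> float:
        if cell in tokens:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise PanelValidationError(
                f"non-numeric cell {cell!r} at sample {row!r}, metabolite {col!r}"
            ) from None

    data = pd.DataFrame(
        {
            col: [convert(v, r, col) for r, v in zip(raw.index, raw[col])]
            for col in raw.columns
        },
        index=raw.index,
    )
    classes = None
    if class_path is not None:
        cls = _read_delimited(class_path)
        classes = dict(zip(cls.iloc[:, 0], cls.iloc[:, 1]))
    return ConcentrationTable(data, classes)


def read_cohort_design(path: str | Path) -> CohortDesign:
    """Read the sample metadata table (columns per ``METADATA_COLUMNS``)."""
    raw = _read_delimited(path).set_index("sample_id")
    for col in ("age", "bmi"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col])
    return CohortDesign(raw)


def filter_by_detection(
    table: ConcentrationTable, min_fraction: float = 0.8
) -> ConcentrationTable:
    """Retain metabolites detected in strictly more than ``min_fraction`` of samples.

    The inequality is strict: a metabolite observed in exactly 80% of the
    samples is dropped at the default threshold.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    keep = table.detection_fraction() > min_fraction
    if not keep.any():
        raise PanelValidationError(
            "the detection filter removed every metabolite; lower min_fraction"
        )
    return ConcentrationTable(table.data.loc[:, keep], table.classes)


def impute_half_min(table: ConcentrationTable) -> ConcentrationTable:
    """Replace missing entries with half the metabolite's minimum observed value."""
    fully_missing = table.data.columns[table.data.isna().all(axis=0)].tolist()
    if fully_missing:
        raise PanelValidationError(
            f"metabolites with no observed value (run the detection filter first): "
            f"{fully_missing}"
        )
    half_min = table.data.min(axis=0, skipna=True) / 2.0
    return ConcentrationTable(table.data.fillna(half_min), table.classes)


def assemble_paired(
    table: ConcentrationTable, design: CohortDesign, stratum: str
) -> PairedDataset:
    """Split a preprocessed stratum table into aligned plasma and JF matrices."""
    uncovered = set(table.sample_ids) - set(design.table.index)
    if uncovered:
        raise PanelValidationError(
            f"samples without metadata: {sorted(uncovered)}"
        )
    if stratum not in design.strata:
        raise PanelValidationError(
            f"stratum {stratum!r} not present in the design (have {design.strata})"
        )
    in_table = set(table.sample_ids)
    sides: dict[str, pd.DataFrame] = {}
    subjects: dict[str, list] = {}
    for comp in COMPARTMENTS:
        ids = [s for s in design.samples_of(stratum, comp) if s in in_table]
        if len(ids) < 4:
            raise PanelValidationError(
                f"stratum {stratum!r} has {len(ids)} {comp} samples; at least 4 "
                "are required (n - 3 must be positive)"
            )
        sides[comp] = table.data.loc[ids]
        subjects[comp] = list(design.table.loc[ids, "subject_id"])
    return PairedDataset(
        stratum=stratum,
        plasma=sides["plasma"],
        jf=sides["JF"],
        plasma_subjects=subjects["plasma"],
        jf_subjects=subjects["JF"],
    )


def preprocess_stratum(
    table: ConcentrationTable,
    design: CohortDesign,
    stratum: str,
    min_fraction: float = 0.8,
    filter_scope: str = "pooled",
) -> PairedDataset:
    """Detection filter, half-minimum imputation and paired assembly for one stratum.

    With the default ``filter_scope="pooled"`` the detection fraction is
    computed over all samples of the stratum (plasma and JF pooled), keeping
    one common metabolite list; ``"per_compartment"`` requires the threshold
    to be passed within each compartment separately (the intersection of the
    two retained lists). The half-minimum is always pooled, so both
    compartments share one concentration floor.
    """
    ids = design.samples_of(stratum)
    ids = [s for s in table.sample_ids if s in set(ids)]
    sub = table.subset_samples(ids)
    if filter_scope == "pooled":
        sub = filter_by_detection(sub, min_fraction)
    elif filter_scope == "per_compartment":
        keep = None
        for comp in COMPARTMENTS:
            comp_ids = [s for s in design.samples_of(stratum, comp) if s in set(ids)]
            frac = sub.subset_samples(comp_ids).detection_fraction()
            mask = frac > min_fraction
            keep = mask if keep is None else (keep & mask)
        if keep is None or not keep.any():
            raise PanelValidationError(
                "the detection filter removed every metabolite; lower min_fraction"
            )
        sub = ConcentrationTable(sub.data.loc[:, keep], sub.classes)
    else:
        raise ValueError(f"unknown filter_scope {filter_scope!r}")
    sub = impute_half_min(sub)
    return assemble_paired(sub, design, stratum)
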