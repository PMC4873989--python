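"""Domain types for the pathway-profiling bioactivity database.

The central object is the :class:`ActivityMatrix` — a dense compounds ×
assay-readouts table of percent-activity values.  Each column is described by
an :class:`AssayDescriptor` (which pathway reporter or proliferation readout
it is), each row by a :class:`CompoundRecord`.  Target annotations for
reference compounds live in an :class:`AnnotationTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table or domain object violates its contract."""


class AssayClass(str, Enum):
    REPORTER = "reporter"
    PROLIFERATION = "proliferation"


class ReadoutMode(str, Enum):
    INHIBITION_WITH_LIGAND = "inhibition_with_ligand"
    ACTIVATION_WITHOUT_LIGAND = "activation_without_ligand"
    VIABILITY = "viability"


#: allowed unit tags for the single-point test concentration
CONCENTRATION_UNITS = ("uM", "ug/mL")


@dataclass(frozen=True)
class AssayDescriptor:
    """One readout column of the panel.

    A reporter-gene assay contributes two readouts per signal: percent
    inhibition measured with ligand stimulation, and percent activation
    (agonism) measured without ligand.  Proliferation assays contribute a
    single viability readout per cell line.
    """

    assay_id: str
    signal_name: str
    assay_class: AssayClass
    cell_line: str
    readout_mode: ReadoutMode
    ligand: str | None = None
    incubation_hours: float = 24.0

    def __post_init__(self) -> None:
        if not self.assay_id:
            raise ValidationError("assay_id must be a non-empty string")
        if self.incubation_hours <= 0:
            raise ValidationError(
                f"assay {self.assay_id!r}: incubation_hours must be positive"
            )
        is_viability = self.readout_mode is ReadoutMode.VIABILITY
        is_prolif = self.assay_class is AssayClass.PROLIFERATION
        if is_viability != is_prolif:
            raise ValidationError(
                f"assay {self.assay_id!r}: readout_mode 'viability' is required "
                "for, and only for, proliferation assays"
            )


# Reporter signals and proliferation cell lines used for the default panel.
_REPORTER_SIGNALS = (
    ("CRE", "forskolin"),
    ("SRE", "PMA"),
    ("NFkB", "TNFa"),
    ("Wnt", "Wnt3a"),
    ("TGFb", "TGFb1"),
    ("NFAT", "ionomycin"),
    ("p53", "etoposide"),
    ("HIF", "DFO"),
    ("Myc", "serum"),
    ("Notch", "DLL4"),
    ("STAT3", "IL-6"),
    ("AP1", "PMA"),
    ("FOXO", "LY294002"),
    ("ERE", "estradiol"),
    ("GRE", "dexamethasone"),
)
_PROLIFERATION_LINES = (
    "MDA-MB-231", "HeLa", "A549", "HCT116", "PC-3", "MCF7", "U2OS", "K562",
)


def default_panel(n_assays: int = 39) -> list[AssayDescriptor]:
    """Build the default assay panel.

    The canonical width is 39 readouts: 15 reporter signals measured in two
    modes (inhibition with ligand, activation without ligand), 8 proliferation
    readouts, and one additional single-mode reporter readout.  Any other
    width is filled by truncating or by appending generic reporter readouts.
    """
    descriptors: list[AssayDescriptor] = []
    for signal, ligand in _REPORTER_SIGNALS:
        descriptors.append(AssayDescriptor(
            assay_id=f"{signal}_inh", signal_name=signal,
            assay_class=AssayClass.REPORTER, cell_line="HEK293",
            readout_mode=ReadoutMode.INHIBITION_WITH_LIGAND, ligand=ligand,
        ))
        descriptors.append(AssayDescriptor(
            assay_id=f"{signal}_act", signal_name=signal,
            assay_class=AssayClass.REPORTER, cell_line="HEK293",
            readout_mode=ReadoutMode.ACTIVATION_WITHOUT_LIGAND, ligand=None,
        ))
    for line in _PROLIFERATION_LINES:
        descriptors.append(AssayDescriptor(
            assay_id=f"prolif_{line}", signal_name="proliferation",
            assay_class=AssayClass.PROLIFERATION, cell_line=line,
            readout_mode=ReadoutMode.VIABILITY,
        ))
    descriptors.append(AssayDescriptor(
        assay_id="SRF_inh", signal_name="SRF",
        assay_class=AssayClass.REPORTER, cell_line="HEK293",
        readout_mode=ReadoutMode.INHIBITION_WITH_LIGAND, ligand="serum",
    ))
    if n_assays < 1:
        raise ValidationError("n_assays must be positive")
    while len(descriptors) < n_assays:
        i = len(descriptors) + 1
        descriptors.append(AssayDescriptor(
            assay_id=f"reporter_{i:02d}_inh", signal_name=f"reporter_{i:02d}",
            assay_class=AssayClass.REPORTER, cell_line="HEK293",
            readout_mode=ReadoutMode.INHIBITION_WITH_LIGAND, ligand="generic",
        ))
    return descriptors[:n_assays]


@dataclass
class CompoundRecord:
    """One library compound: identity, optional structure and annotation."""

    compound_id: str
    name: str | None = None
    library: str | None = None
    test_concentration: float | None = None
    concentration_unit: str | None = None
    smiles: str | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be a non-empty string")
        if self.test_concentration is not None:
            if self.test_concentration <= 0:
                raise ValidationError(
                    f"compound {self.compound_id!r}: test_concentration must be "
                    "positive"
                )
            if self.concentration_unit not in CONCENTRATION_UNITS:
                raise ValidationError(
                    f"compound {self.compound_id!r}: concentration unit must be "
                    f"one of {CONCENTRATION_UNITS}, got {self.concentration_unit!r}"
                )


class AnnotationTable(Mapping[str, str]):
    """compound_id → target/MOA label, with optional free-text notes."""

    def __init__(self, labels: Mapping[str, str],
                 notes: Mapping[str, str] | None = None) -> None:
        self._labels = dict(labels)
        self._notes = dict(notes or {})
        for cid, label in self._labels.items():
            if not cid or not label:
                raise ValidationError(
                    f"annotation {cid!r} -> {label!r}: empty key or label"
                )

    def __getitem__(self, compound_id: str) -> str:
        return self._labels[compound_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def note(self, compound_id: str) -> str | None:
        return self._notes.get(compound_id)

    def validate_against(self, records: Iterable[CompoundRecord]) -> None:
        """Every annotated id must resolve to a compound record."""
        known = {r.compound_id for r in records}
        missing = sorted(set(self._labels) - known)
        if missing:
            raise ValidationError(
                f"annotations refer to unknown compound ids: {missing[:10]}"
            )


class ActivityMatrix:
    """Dense compounds × assay-readouts percent-activity table.

    Values are plain percent-activity numbers (no unit conversion happens
    here).  ``normalized`` records whether per-assay Z-scoring has been
    applied; if so ``normalization_params`` holds the per-column mean and
    (population) standard deviation that were removed, plus a flag for
    zero-variance columns that were mapped to zeros.
    """

    def __init__(self, values: pd.DataFrame,
                 assays: list[AssayDescriptor] | None = None,
                 normalized: bool = False,
                 normalization_params: pd.DataFrame | None = None) -> None:
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate compound_id(s): {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate assay_id(s): {dups}")
        if values.shape[1] < 2:
            raise ValidationError(
                f"activity matrix needs at least 2 assay columns, got "
                f"{values.shape[1]}"
            )
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = values.columns[
                [not np.issubdtype(d, np.number) for d in values.dtypes]
            ].tolist()
            raise ValidationError(f"non-numeric assay column(s): {bad}")
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at compound {values.index[r]!r}, "
                f"assay {values.columns[c]!r}"
            )
        if assays is not None:
            if len(assays) != values.shape[1]:
                raise ValidationError(
                    f"panel has {len(assays)} descriptors but matrix has "
                    f"{values.shape[1]} columns"
                )
            for desc, col in zip(assays, values.columns):
                if desc.assay_id != str(col):
                    raise ValidationError(
                        f"panel/matrix column mismatch: {desc.assay_id!r} vs "
                        f"{col!r}"
                    )
        self.values = values.astype(float)
        self.assays = assays
        self.normalized = normalized
        self.normalization_params = normalization_params
        if normalized:
            self._check_normalized()

    def _check_normalized(self) -> None:
        arr = self.values.to_numpy()
        means = arr.mean(axis=0)
        if np.any(np.abs(means) >= 1e-9):
            raise ValidationError("normalized matrix has a column mean off zero")
        sds = arr.std(axis=0)
        constant = np.zeros(arr.shape[1], dtype=bool)
        if self.normalization_params is not None:
            constant = self.normalization_params["zero_variance"].to_numpy(bool)
        bad = ~constant & (np.abs(sds - 1.0) >= 1e-9)
        if np.any(bad):
            raise ValidationError(
                "normalized matrix has a non-constant column with sd != 1"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    @property
    def compound_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def assay_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def profile(self, compound_id: str) -> np.ndarray:
        """Activity profile (row vector) of one compound."""
        try:
            return self.values.loc[compound_id].to_numpy(float)
        except KeyError:
            raise KeyError(f"unknown compound_id {compound_id!r}") from None

    def __repr__(self) -> str:
        n, m = self.shape
        state = "normalized" if self.normalized else "raw"
        return f"ActivityMatrix({n} compounds x {m} assays, {state})"
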