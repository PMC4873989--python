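"""Synthetic bioactivity databases with planted mechanism-of-action classes.

Real pathway-profiling databases are proprietary, so every downstream stage
is exercised on simulated data with known ground truth.  The generative
model:

* each MOA class ``k`` has a fixed *signature* vector over the assay panel —
  a sparse subset of readouts (``signature_sparsity`` of the panel) carrying
  activity of magnitude ``signature_scale`` with random sign (readouts mix
  inhibition and activation, so signs are arbitrary);
* a class member's profile is the signature plus iid Gaussian noise per
  readout; inactive compounds are pure noise;
* a compound shows "detectable activity" when some readout exceeds
  ``3 x noise_sd`` in magnitude.

The default specification emulates the scale of a real screening database:
1910 compounds over a 39-readout panel with roughly 70% of compounds showing
detectable activity in at least one assay.

Structure generation is decoupled from activity on purpose: *diverse* mode
plants low within-class Tanimoto (structurally unrelated compounds sharing a
mechanism), *analog* mode plants high within-class Tanimoto (a scaffold
series).  This is what lets tests separate bioactivity similarity from
structural similarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (ActivityMatrix, AnnotationTable, CompoundRecord,
                   ValidationError, default_panel)
from .similarity import Fingerprint


@dataclass(frozen=True)
class PanelSimSpec:
    """Parameters of a planted-class activity database.

    Defaults give 13 classes x 98 members + 636 inactives = 1910 compounds
    on a 39-readout panel.  With ``noise_sd = 10`` percent-activity units and
    3-sigma detection, pure-noise compounds clear the detection threshold in
    at least one of 39 readouts about 10% of the time, so the expected
    detectable-active fraction is (1274 + 0.10 * 636) / 1910 ~ 0.70.
    ``signature_sparsity = 0.25`` makes a class signature span ~10 readouts —
    e.g. a cytotoxic mechanism lighting up the proliferation readouts plus a
    few stress-responsive reporters.
    """

    n_classes: int = 13
    n_per_class: int = 98
    n_inactive: int = 636
    n_assays: int = 39
    signature_sparsity: float = 0.25
    signature_scale: float = 50.0
    noise_sd: float = 10.0
    annotated_fraction: float = 1.0
    active_fraction_target: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_per_class < 1:
            raise ValidationError("n_classes and n_per_class must be positive")
        if self.n_inactive < 0:
            raise ValidationError("n_inactive must be non-negative")
        if self.n_assays < 2:
            raise ValidationError("n_assays must be at least 2")
        if not 0.0 < self.signature_sparsity <= 1.0:
            raise ValidationError("signature_sparsity must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ValidationError("annotated_fraction must be in [0, 1]")
        if not 0.0 <= self.active_fraction_target <= 1.0:
            raise ValidationError("active_fraction_target must be in [0, 1]")

    @property
    def n_compounds(self) -> int:
        return self.n_classes * self.n_per_class + self.n_inactive


INACTIVE_LABEL = "inactive"


@dataclass
class SimTruth:
    """Ground truth of a generated database."""

    labels: dict[str, str]                 # compound_id -> class label
    signatures: dict[str, np.ndarray]      # class label -> signature vector
    assay_ids: list[str]
    noise_sd: float

    def members(self, label: str) -> list[str]:
        return [cid for cid, lbl in self.labels.items() if lbl == label]

    def to_json(self) -> str:
        payload = {
            "labels": self.labels,
            "signatures": {k: list(map(float, v))
                           for k, v in self.signatures.items()},
            "assay_ids": self.assay_ids,
            "noise_sd": self.noise_sd,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        return cls(
            labels=dict(payload["labels"]),
            signatures={k: np.asarray(v, dtype=float)
                        for k, v in payload["signatures"].items()},
            assay_ids=list(payload["assay_ids"]),
            noise_sd=float(payload["noise_sd"]),
        )


def _class_names(n: int, names: list[str] | None) -> list[str]:
    if names is not None:
        if len(names) != n:
            raise ValidationError(f"need {n} class names, got {len(names)}")
        return list(names)
    return [f"moa_{k + 1:02d}" for k in range(n)]


def generate_panel(spec: PanelSimSpec,
                   class_names: list[str] | None = None
                   ) -> tuple[ActivityMatrix, list[CompoundRecord],
                              AnnotationTable, SimTruth]:
    """Generate a planted-class activity database.

    Deterministic given ``spec`` (the seed is part of the spec).  Annotations
    are the true class labels for ``annotated_fraction`` of each class's
    members; inactive compounds are never annotated.
    """
    rng = np.random.default_rng(spec.seed)
    names = _class_names(spec.n_classes, class_names)
    panel = default_panel(spec.n_assays)
    assay_ids = [d.assay_id for d in panel]

    n_sig = max(1, int(round(spec.signature_sparsity * spec.n_assays)))
    signatures: dict[str, np.ndarray] = {}
    for name in names:
        sig = np.zeros(spec.n_assays)
        idx = rng.choice(spec.n_assays, size=n_sig, replace=False)
        sig[idx] = spec.signature_scale * rng.choice([-1.0, 1.0], size=n_sig)
        signatures[name] = sig

    total = spec.n_compounds
    width = len(str(total))
    compound_ids = [f"C{i + 1:0{width}d}" for i in range(total)]
    labels: dict[str, str] = {}
    profiles = np.empty((total, spec.n_assays))
    records: list[CompoundRecord] = []
    ann: dict[str, str] = {}

    pos = 0
    for name in names:
        member_ids = compound_ids[pos:pos + spec.n_per_class]
        n_annotated = int(round(spec.annotated_fraction * spec.n_per_class))
        annotated = set(rng.choice(spec.n_per_class, size=n_annotated,
                                   replace=False))
        for j, cid in enumerate(member_ids):
            labels[cid] = name
            profiles[pos + j] = signatures[name] + rng.normal(
                0.0, spec.noise_sd, spec.n_assays)
            is_annotated = j in annotated
            records.append(CompoundRecord(
                compound_id=cid, library="synthetic",
                test_concentration=3.0, concentration_unit="uM",
                annotation=name if is_annotated else None))
            if is_annotated:
                ann[cid] = name
        pos += spec.n_per_class
    for cid in compound_ids[pos:]:
        labels[cid] = INACTIVE_LABEL
        profiles[compound_ids.index(cid)] = rng.normal(
            0.0, spec.noise_sd, spec.n_assays)
        records.append(CompoundRecord(
            compound_id=cid, library="synthetic",
            test_concentration=3.0, concentration_unit="uM"))

    values = pd.DataFrame(profiles, index=compound_ids, columns=assay_ids)
    matrix = ActivityMatrix(values, assays=panel)
    truth = SimTruth(labels=labels, signatures=signatures,
                     assay_ids=assay_ids, noise_sd=spec.noise_sd)
    return matrix, records, AnnotationTable(ann), truth


def measure_active_fraction(matrix: ActivityMatrix, noise_sd: float,
                            k_sigma: float = 3.0) -> float:
    """Fraction of compounds with detectable activity in >= 1 readout.

    "Detectable" means |percent activity| >= k_sigma * noise_sd; applied to
    the raw (un-normalized) matrix.
    """
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive to define detection")
    X = np.abs(matrix.values.to_numpy(float))
    return float(np.mean((X >= k_sigma * noise_sd).any(axis=1)))


def generate_query(truth: SimTruth, class_label: str, noise_sd: float,
                   seed: int) -> np.ndarray:
    """A query compound's profile: its class signature plus fresh noise."""
    if class_label not in truth.signatures:
        raise ValidationError(
            f"unknown class label {class_label!r}; "
            f"known: {sorted(truth.signatures)}"
        )
    rng = np.random.default_rng(seed)
    sig = truth.signatures[class_label]
    return sig + rng.normal(0.0, noise_sd, sig.size)


def generate_structures(truth: SimTruth, within_class_similarity: str,
                        seed: int, n_bits: int = 2048, n_set: int = 64,
                        mutation_rate: float = 0.05
                        ) -> dict[str, Fingerprint]:
    """Plant structural fingerprints consistent (or not) with the classes.

    ``diverse``: every compound gets an independent random bit-set, so
    within-class Tanimoto matches the unrelated-structure expectation
    (~ n_set / (2 * n_bits - n_set), about 0.016 at the defaults) — compounds
    sharing a mechanism but not a scaffold.

    ``analog``: each class has a core bit-set; members mutate each core bit
    with probability ``mutation_rate`` (dropping it and gaining a random bit
    elsewhere), giving expected pairwise Tanimoto well above 0.6 at the
    default rate — a scaffold series.  Inactive compounds are always random.
    """
    if within_class_similarity not in ("analog", "diverse"):
        raise ValidationError(
            "within_class_similarity must be 'analog' or 'diverse', got "
            f"{within_class_similarity!r}"
        )
    if not 0 < n_set <= n_bits:
        raise ValidationError("need 0 < n_set <= n_bits")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValidationError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def random_bits() -> frozenset[int]:
        return frozenset(rng.choice(n_bits, size=n_set, replace=False).tolist())

    cores = {}
    if within_class_similarity == "analog":
        for label in sorted(truth.signatures):
            cores[label] = random_bits()

    fingerprints: dict[str, Fingerprint] = {}
    for cid in sorted(truth.labels):
        label = truth.labels[cid]
        if within_class_similarity == "diverse" or label == INACTIVE_LABEL:
            bits = random_bits()
        else:
            bits = set(cores[label])
            for b in sorted(bits):
                if rng.random() < mutation_rate:
                    bits.discard(b)
                    bits.add(int(rng.integers(n_bits)))
            bits = frozenset(bits)
        fingerprints[cid] = Fingerprint(bits=bits, n_bits=n_bits)
    return fingerprints


def generate_dose_response(bottom: float, top: float, ic50: float,
                           hill: float, concentrations, noise_sd: float,
                           seed: int) -> pd.DataFrame:
    """Noisy 4PL curve: columns (conc, response)."""
    c = np.asarray(concentrations, dtype=float)
    if ic50 <= 0:
        raise ValidationError("ic50 must be positive")
    if np.any(c <= 0):
        raise ValidationError("concentrations must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    response = (bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)
                + rng.normal(0.0, noise_sd, c.size))
    return pd.DataFrame({"conc": c, "response": response})


def half_log_grid(center: float, n_points: int = 8) -> np.ndarray:
    """Half-log (sqrt(10)-spaced) concentration grid centered on ``center``."""
    offsets = np.arange(n_points) - (n_points - 1) / 2
    return center * (10.0 ** (offsets / 2.0))


def generate_screen_table(n_compounds: int, hit_fraction: float,
                          hit_fold_mean: float, cells_per_well: int,
                          noise: float, seed: int,
                          base_area: float = 1500.0,
                          n_vehicle_wells: int = 16
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-cell area tables for a synthetic high-content senescence screen.

    Cell areas are lognormal (strictly positive, right-skewed, like real
    morphology measurements) with log-scale sd ``noise`` around a mean of
    ``base_area`` (arbitrary area units, think um^2); planted hits scale the
    arm mean by ``hit_fold_mean``.  Returns (treated, vehicle, truth):
    treated has columns (compound_id, well, cell_id, area); vehicle pools
    ``n_vehicle_wells`` wells; truth has (compound_id, is_hit, true_fold).
    """
    if not 0.0 <= hit_fraction <= 1.0:
        raise ValidationError("hit_fraction must be in [0, 1]")
    if n_compounds < 1 or cells_per_well < 1:
        raise ValidationError("n_compounds and cells_per_well must be positive")
    if hit_fold_mean <= 0 or base_area <= 0:
        raise ValidationError("fold and base area must be positive")
    if noise < 0:
        raise ValidationError("noise must be non-negative")
    rng = np.random.default_rng(seed)

    n_hits = int(round(hit_fraction * n_compounds))
    hit_idx = set(rng.choice(n_compounds, size=n_hits, replace=False).tolist())

    def lognormal_areas(mean_area: float, n: int) -> np.ndarray:
        mu = np.log(mean_area) - noise ** 2 / 2.0  # arithmetic mean = mean_area
        return rng.lognormal(mu, noise, n)

    width = len(str(n_compounds))
    treated_rows = []
    truth_rows = []
    for i in range(n_compounds):
        cid = f"S{i + 1:0{width}d}"
        is_hit = i in hit_idx
        fold = hit_fold_mean if is_hit else 1.0
        areas = lognormal_areas(base_area * fold, cells_per_well)
        for j, a in enumerate(areas):
            treated_rows.append((cid, f"W{i + 1}", j, a))
        truth_rows.append((cid, is_hit, fold))
    vehicle_rows = []
    for w in range(n_vehicle_wells):
        areas = lognormal_areas(base_area, cells_per_well)
        for j, a in enumerate(areas):
            vehicle_rows.append((f"V{w + 1}", j, a))

    treated = pd.DataFrame(treated_rows,
                           columns=["compound_id", "well", "cell_id", "area"])
    vehicle = pd.DataFrame(vehicle_rows, columns=["well", "cell_id", "area"])
    truth = pd.DataFrame(truth_rows,
                         columns=["compound_id", "is_hit", "true_fold"])
    return treated, vehicle, truth


def generate_target_id_scenario(seed: int,
                                n_neighbors: int = 12,
                                n_target_annotated: int = 10,
                                target_label: str = "tubulin disruptor",
                                n_background_classes: int = 12,
                                n_per_class: int = 98,
                                n_inactive: int = 722,
                                neighbor_noise_frac: float = 0.1,
                                base_spec: PanelSimSpec | None = None):
    """Desk-scale analogue of a profile-based target-identification run.

    Builds a database of background MOA classes plus inactives, then plants
    ``n_neighbors`` compounds sharing the query's (held-out) class signature,
    ``n_target_annotated`` of them annotated with ``target_label`` and the
    rest with unrelated annotations.  The query is a fresh noisy draw of the
    same signature.  Neighbor and query noise is ``neighbor_noise_frac`` of
    the signature scale, putting within-class Rp deep in the
    high-similarity regime while background compounds stay uncorrelated.

    Returns (matrix, annotations, query_profile, truth, target_label).
    """
    spec = base_spec or PanelSimSpec(
        n_classes=n_background_classes, n_per_class=n_per_class,
        n_inactive=n_inactive, seed=seed)
    matrix, records, ann, truth = generate_panel(spec)
    rng = np.random.default_rng(spec.seed + 987_001)

    n_sig = max(1, int(round(spec.signature_sparsity * spec.n_assays)))
    sig = np.zeros(spec.n_assays)
    idx = rng.choice(spec.n_assays, size=n_sig, replace=False)
    sig[idx] = spec.signature_scale * rng.choice([-1.0, 1.0], size=n_sig)
    noise_sd = neighbor_noise_frac * spec.signature_scale

    other_labels = ["P-selectin inhibitor", "IGF2 signaling modulator",
                    "kinase inhibitor", "ion channel blocker"]
    rows = {}
    labels = dict(truth.labels)
    ann_map = dict(ann)
    for i in range(n_neighbors):
        cid = f"N{i + 1:03d}"
        rows[cid] = sig + rng.normal(0.0, noise_sd, spec.n_assays)
        labels[cid] = target_label
        if i < n_target_annotated:
            ann_map[cid] = target_label
        else:
            ann_map[cid] = other_labels[(i - n_target_annotated)
                                        % len(other_labels)]
    planted = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=matrix.assay_ids)
    values = pd.concat([matrix.values, planted])
    full = ActivityMatrix(values, assays=matrix.assays)
    signatures = dict(truth.signatures)
    signatures[target_label] = sig
    full_truth = SimTruth(labels=labels, signatures=signatures,
                          assay_ids=truth.assay_ids, noise_sd=spec.noise_sd)
    query = sig + rng.normal(0.0, noise_sd, spec.n_assays)
    return full, AnnotationTable(ann_map), query, full_truth, target_label
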