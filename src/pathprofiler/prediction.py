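"""Target prediction by annotated nearest neighbors in bioactivity space.

The procedure: correlate a query compound's activity profile against every
compound in the database, keep the neighbors whose Pearson Rp exceeds a
threshold (strictly above; 0.8 by default), and call the query's target as
the majority annotation among the annotated neighbors.  Structural
similarity (Tanimoto) is reported alongside for context but carries no
weight in the call — the whole point of profile-based MOA inference is that
it works when the structures are dissimilar.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ActivityMatrix, AnnotationTable, ValidationError
from .similarity import Fingerprint, pairwise_rp, tanimoto

NO_PREDICTION = "no_prediction"


@dataclass(frozen=True)
class NeighborRow:
    compound_id: str
    rp: float
    tanimoto: float | None = None
    annotation: str | None = None


@dataclass
class SimilarityReport:
    """Ranked above-threshold neighbors of one query compound."""

    query_id: str
    rows: list[NeighborRow]
    threshold: float

    def __post_init__(self) -> None:
        keys = [(-r.rp, r.compound_id) for r in self.rows]
        if keys != sorted(keys):
            raise ValidationError(
                "report rows must be sorted by Rp descending (ties by id)"
            )
        below = [r.compound_id for r in self.rows if r.rp <= self.threshold]
        if below:
            raise ValidationError(
                f"rows at or below threshold {self.threshold}: {below[:5]}"
            )

    @property
    def n_neighbors(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.compound_id, r.rp, r.tanimoto, r.annotation) for r in self.rows],
            columns=["compound_id", "rp", "tanimoto", "annotation"],
        )


@dataclass
class TargetPrediction:
    """Voted target call for one query."""

    query_id: str
    predicted_target: str
    vote_fraction: float
    n_neighbors: int
    n_annotated: int
    supporting_compound_ids: list[str] = field(default_factory=list)
    tied_labels: list[str] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        """Fraction of retained neighbors that carry any annotation."""
        return self.n_annotated / self.n_neighbors if self.n_neighbors else 0.0


def rank_neighbors(query: np.ndarray, db: ActivityMatrix,
                   threshold: float = 0.8, *,
                   query_id: str = "query",
                   exclude_ids: set[str] | None = None,
                   annotations: AnnotationTable | None = None,
                   query_fingerprint: Fingerprint | None = None,
                   fingerprints: dict[str, Fingerprint] | None = None
                   ) -> SimilarityReport:
    """Database neighbors with Rp strictly above ``threshold``.

    Rows with undefined correlation (constant profiles) are dropped.  The
    query itself is excluded when its id appears in the database (or in
    ``exclude_ids``).  Sorting is by Rp descending with ties broken by
    compound_id for reproducibility.
    """
    if not -1.0 < threshold < 1.0:
        raise ValidationError(f"threshold must be in (-1, 1), got {threshold}")
    rp = pairwise_rp(query, db)
    skip = set(exclude_ids or ()) | {query_id}
    rows: list[NeighborRow] = []
    for cid, value in rp.items():
        cid = str(cid)
        if cid in skip or not np.isfinite(value) or value <= threshold:
            continue
        tan = None
        if query_fingerprint is not None and fingerprints is not None:
            fp = fingerprints.get(cid)
            if fp is not None:
                tan = tanimoto(query_fingerprint, fp)
        ann = annotations.get(cid) if annotations is not None else None
        rows.append(NeighborRow(cid, float(value), tan, ann))
    rows.sort(key=lambda r: (-r.rp, r.compound_id))
    return SimilarityReport(query_id=query_id, rows=rows, threshold=threshold)


def predict_target(report: SimilarityReport,
                   annotations: AnnotationTable | None = None
                   ) -> TargetPrediction:
    """Majority-annotation vote among the retained neighbors.

    The vote denominator is the number of *annotated* neighbors: compounds
    without a target annotation carry no target signal and abstain.  An
    empty report, no annotated neighbor, or a tied vote yields
    ``no_prediction`` (ties list the tied labels); degenerate inputs are
    results, not errors.
    """
    labels: dict[str, str] = {}
    for row in report.rows:
        ann = row.annotation
        if ann is None and annotations is not None:
            ann = annotations.get(row.compound_id)
        if ann is not None:
            labels[row.compound_id] = ann

    n_neighbors = report.n_neighbors
    if not labels:
        return TargetPrediction(report.query_id, NO_PREDICTION, 0.0,
                                n_neighbors, 0)
    counts = Counter(labels.values())
    top_count = max(counts.values())
    winners = sorted(lbl for lbl, c in counts.items() if c == top_count)
    n_annotated = len(labels)
    vote_fraction = top_count / n_annotated
    if len(winners) > 1:
        return TargetPrediction(report.query_id, NO_PREDICTION, vote_fraction,
                                n_neighbors, n_annotated, tied_labels=winners)
    target = winners[0]
    supporting = sorted(cid for cid, lbl in labels.items() if lbl == target)
    return TargetPrediction(report.query_id, target, vote_fraction,
                            n_neighbors, n_annotated,
                            supporting_compound_ids=supporting)


def evaluate_prediction_accuracy(db: ActivityMatrix,
                                 annotations: AnnotationTable,
                                 truth,
                                 noise_levels: list[float],
                                 n_queries: int = 100,
                                 threshold: float = 0.8,
                                 seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo recovery rate of the neighbor-vote procedure.

    For each noise level, ``n_queries`` synthetic queries are drawn from the
    planted MOA classes of ``truth`` (a :class:`~pathprofiler.synthetic.SimTruth`),
    ranked against ``db`` and voted; the table reports the fraction of
    queries whose call equals their true class and the fraction with no
    call at all.
    """
    from .synthetic import generate_query

    rng = np.random.default_rng(seed)
    class_labels = sorted(truth.signatures)
    records = []
    for noise_sd in noise_levels:
        correct = 0
        no_pred = 0
        for _ in range(n_queries):
            label = class_labels[rng.integers(len(class_labels))]
            qseed = int(rng.integers(2**31 - 1))
            query = generate_query(truth, label, noise_sd, qseed)
            report = rank_neighbors(query, db, threshold,
                                    annotations=annotations)
            pred = predict_target(report)
            if pred.predicted_target == label:
                correct += 1
            elif pred.predicted_target == NO_PREDICTION:
                no_pred += 1
        records.append({
            "noise_sd": noise_sd,
            "threshold": threshold,
            "n_queries": n_queries,
            "accuracy": correct / n_queries,
            "no_prediction_rate": no_pred / n_queries,
            "seed": seed,
        })
    return pd.DataFrame.from_records(records)
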