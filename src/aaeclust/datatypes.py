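"""Core in-memory containers.

The pipeline's data flow is::

    PeakMatrix (samples x peaks) --embed--> latent Z --cluster--> ClusterSolution
                                                        |
    SurvivalTable (clinical) ---------------------------+--> evaluation

Peak coordinates follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ShapeError, ValidationError

__all__ = [
    "PeakRecord",
    "PeakMatrix",
    "SurvivalTable",
    "ClusterSolution",
]


@dataclass(frozen=True)
class PeakRecord:
    """A fixed genomic interval of accessible chromatin.

    Coordinates are 0-based half-open, so ``width = end - start``.
    ``linked_gene`` is the annotation-supplied regulatory gene, if any.
    """

    chrom: str
    start: int
    end: int
    linked_gene: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"peak {self.chrom}:{self.start}-{self.end} has non-positive width"
            )

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.end - self.start

    @classmethod
    def from_peak_id(cls, peak_id: str, linked_gene: str | None = None) -> "PeakRecord":
        """Parse a ``chrom:start-end`` identifier back into a record."""
        try:
            chrom, span = peak_id.rsplit(":", 1)
            start_s, end_s = span.split("-")
            return cls(chrom, int(start_s), int(end_s), linked_gene)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"malformed peak id {peak_id!r}") from exc


@dataclass
class PeakMatrix:
    """Nonnegative score matrix, samples x peaks, with aligned peak records."""

    values: np.ndarray
    sample_ids: list[str]
    peaks: list[PeakRecord]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("values must be a 2-D samples x features array")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.peaks) != p:
            raise ValidationError(f"{len(self.peaks)} peak records for {p} features")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise ValidationError("matrix contains missing values")
        if (self.values < 0).any():
            raise ValidationError("matrix contains negative values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]


@dataclass
class SurvivalTable:
    """Right-censored follow-up with optional clinical covariates.

    ``event`` is 1 when death was observed; ``time`` is days to death for
    events and days to last follow-up for censored samples. ``covariates``
    is a per-sample DataFrame and ``covariate_types`` tags each column as
    ``"categorical"`` or ``"continuous"``.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariate_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ShapeError("time/event must align with sample_ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in clinical table")
        if (self.time <= 0).any():
            bad = [s for s, t in zip(self.sample_ids, self.time) if t <= 0]
            raise ValidationError(f"non-positive follow-up time for samples {bad}")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        if len(self.covariates) not in (0, n):
            raise ShapeError("covariate rows must align with sample_ids")
        for col in self.covariates.columns:
            kind = self.covariate_types.get(col)
            if kind not in ("categorical", "continuous"):
                raise ValidationError(
                    f"covariate {col!r} must be tagged categorical or continuous"
                )

    def aligned_to(self, sample_ids: list[str]) -> "SurvivalTable":
        """Reorder to match another artifact's sample ids (exact string match)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"clinical table lacks samples {missing[:5]}")
        order = [index[s] for s in sample_ids]
        cov = (
            self.covariates.iloc[order].reset_index(drop=True)
            if len(self.covariates)
            else self.covariates
        )
        return SurvivalTable(
            list(sample_ids),
            self.time[order],
            self.event[order],
            cov,
            dict(self.covariate_types),
        )


@dataclass
class ClusterSolution:
    """Hard labels plus the posterior responsibilities they came from."""

    sample_ids: list[str]
    labels: np.ndarray
    posteriors: np.ndarray | None = None
    k: int | None = None
    db_score: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.sample_ids)
        if self.labels.shape != (n,):
            raise ShapeError("labels must align with sample_ids")
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=float)
            if self.posteriors.shape[0] != n:
                raise ShapeError("posterior rows must align with sample_ids")
        if self.k is None:
            self.k = int(len(np.unique(self.labels))) if n else 0

    def label_names(self) -> list[str]:
        """1-based display names C1..CK for the 0-based internal labels."""
        return [f"C{int(l) + 1}" for l in self.labels]
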