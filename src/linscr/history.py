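"""Individual x detector x occasion detection histories for count detectors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


SEXES = ("female", "male", "unknown")


@dataclass
class DetectionHistory:
    """Nonnegative detection counts ``n[i, k, o]`` with per-individual sex labels.

    Latrines are count detectors: an individual can be detected several
    times at the same detector within one occasion, so entries may exceed 1.
    Every retained individual must have at least one detection.
    """

    counts: np.ndarray                 # (n_ind, K, O) nonnegative ints
    sexes: list[str]                   # each in SEXES
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, int)
        if self.counts.ndim != 3:
            raise ValueError("counts must be individuals x detectors x occasions")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.sexes) != self.counts.shape[0]:
            raise ValueError("one sex label per individual required")
        for s in self.sexes:
            if s not in SEXES:
                raise ValueError(f"unknown sex label {s!r}")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i}" for i in range(self.counts.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.counts.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.counts.shape[2]

    @property
    def total_detections(self) -> int:
        return int(self.counts.sum())

    def n_recaptures(self) -> int:
        """Detections beyond each individual's first."""
        return int(self.total_detections - self.n_individuals)

    def n_spatial_recaptures(self) -> int:
        """Detections at detectors other than each individual's first detector.

        The first detector is the one where the individual was first detected
        (earliest occasion; lowest detector index on ties).
        """
        out = 0
        for i in range(self.n_individuals):
            ko = np.argwhere(self.counts[i] > 0)
            if len(ko) == 0:
                continue
            first_det = ko[np.lexsort((ko[:, 0], ko[:, 1]))[0], 0]
            out += int(self.counts[i].sum() - self.counts[i, first_det].sum())
        return out

    def drop_empty(self) -> "DetectionHistory":
        keep = self.counts.sum(axis=(1, 2)) > 0
        return DetectionHistory(
            counts=self.counts[keep],
            sexes=[s for s, k in zip(self.sexes, keep) if k],
            individual_ids=[i for i, k in zip(self.individual_ids, keep) if k],
        )
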