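"""In-memory containers for windowed multi-sensor context datasets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class LabelsHiddenError(RuntimeError):
    """Raised when code tries to read labels from a label-hidden dataset.

    Target-domain labels exist only for evaluation; the training API must
    never see them, and this error is the enforcement mechanism.
    """


@dataclass
class DomainSample:
    """One fixed-length window: raw [3 sensors, 3 axes, T], aux scalars, labels."""

    raw: np.ndarray
    aux: np.ndarray
    labels: np.ndarray | None
    subject_id: int
    domain: str


@dataclass
class DomainDataset:
    """A collection of windows from one domain (source or target).

    ``labels`` is a guarded accessor: datasets opened with labels hidden raise
    :class:`LabelsHiddenError` on access, so leakage of target labels into
    training is a hard error rather than a silent bug.
    """

    raw: np.ndarray                      # [N, 3, 3, T]
    aux: np.ndarray                      # [N, A]
    subject_ids: np.ndarray              # [N]
    domain: str
    label_names: list[str]
    _labels: np.ndarray | None = None    # [N, L] binary
    labels_hidden: bool = False
    features: np.ndarray | None = None   # [N, F], filled by featurization
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.raw.ndim != 4 or self.raw.shape[1:3] != (3, 3):
            raise ValueError("raw must have shape [N, 3, 3, T]")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("raw signal contains non-finite values")
        if self._labels is not None:
            if self._labels.shape[0] != self.raw.shape[0]:
                raise ValueError("labels/raw length mismatch")
            uniq = np.unique(self._labels)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("labels must be binary")

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    def __len__(self) -> int:
        return self.n

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    @property
    def labels(self) -> np.ndarray:
        if self.labels_hidden or self._labels is None:
            raise LabelsHiddenError(
                f"labels of the {self.domain!r} dataset are hidden from this accessor")
        return self._labels

    def without_labels(self) -> "DomainDataset":
        """A view of this dataset whose label accessor always raises."""
        return replace(self, _labels=None, labels_hidden=True)

    def subset(self, idx: np.ndarray) -> "DomainDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            raw=self.raw[idx],
            aux=self.aux[idx],
            subject_ids=self.subject_ids[idx],
            _labels=None if self._labels is None else self._labels[idx],
            features=None if self.features is None else self.features[idx],
        )

    def sample(self, i: int) -> DomainSample:
        return DomainSample(
            raw=self.raw[i],
            aux=self.aux[i],
            labels=None if (self._labels is None or self.labels_hidden) else self._labels[i],
            subject_id=int(self.subject_ids[i]),
            domain=self.domain,
        )
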