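"""Tabular two-class datasets: delimited I/O, min-max scaling, splits, synthesis.

Clinical benchmark tables of the UCI ``.data`` style are plain delimited
text, one record per line, with a class label in one column.  Labels are
stored twice: the raw encoding as found in the file (e.g. ``1`` = benign,
``2`` = malignant) and the mapped ``{+1, -1}`` encoding that the SVM
machinery requires.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledDataset",
    "SplitSpec",
    "NormalizationParams",
    "read_delimited",
    "write_delimited",
    "normalize_minmax",
    "apply_normalization",
    "split",
    "generate_synthetic",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature (min, max) pairs fitted on a training split."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def n_features(self) -> int:
        return self.mins.shape[0]


@dataclass
class LabeledDataset:
    """Feature matrix with ``{+1, -1}`` labels.

    Parameters
    ----------
    features : (n_samples, n_features) float array.
    labels : (n_samples,) int array, every entry +1 or -1.
    raw_labels : original label encoding as read from file (defaults to a
        copy of ``labels``).
    feature_names : optional identifiers, one per column.
    normalization : the (min, max) pairs used to scale ``features``, or
        ``None`` if the data is unscaled.
    """

    features: np.ndarray
    labels: np.ndarray
    raw_labels: np.ndarray = None
    feature_names: list[str] = None
    normalization: NormalizationParams | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError(
                f"{self.labels.shape[0]} labels for {self.features.shape[0]} rows"
            )
        if not np.all(np.isin(self.labels, (1, -1))):
            raise ValueError("labels must be +1 or -1")
        if self.raw_labels is None:
            self.raw_labels = self.labels.copy()
        else:
            self.raw_labels = np.asarray(self.raw_labels)
        if self.feature_names is None:
            self.feature_names = [f"x{j}" for j in range(self.features.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, indices: np.ndarray) -> "LabeledDataset":
        """Row subset preserving all metadata."""
        indices = np.asarray(indices)
        return LabeledDataset(
            features=self.features[indices],
            labels=self.labels[indices],
            raw_labels=self.raw_labels[indices],
            feature_names=list(self.feature_names),
            normalization=self.normalization,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition request.

    ``n_train`` rows go to the training set; the remainder is the test set.
    Stratified sampling keeps the class ratio of the full table within
    rounding in both parts.
    """

    n_train: int
    stratified: bool = True
    seed: int = 0
    order: str = "random"  # "random" | "first-n"

    def __post_init__(self) -> None:
        if self.n_train < 1:
            raise ValueError("n_train must be positive")
        if self.order not in ("random", "first-n"):
            raise ValueError(f"unknown split order {self.order!r}")


class ParseError(ValueError):
    """A delimited file violated the expected record layout."""


def read_delimited(
    path,
    label_column: int = -1,
    label_map: dict | None = None,
    delimiter: str | None = ",",
    missing_policy: str = "error",
    missing_token: str = "?",
    header: bool = False,
) -> LabeledDataset:
    """Read a UCI-style delimited table into a :class:`LabeledDataset`.

    Parameters
    ----------
    label_column : index of the class column (default last).
    label_map : mapping from raw label string/number to +1/-1.  Default
        ``{"1": +1, "2": -1}``, the benign/malignant encoding of the UCI
        clinical tables.
    delimiter : field separator; ``None`` splits on any whitespace.
    missing_policy : ``"error"`` (default) or ``"drop"`` rows containing
        ``missing_token``.
    """
    if label_map is None:
        label_map = {"1": 1, "2": -1}
    label_map = {str(k): v for k, v in label_map.items()}

    with open(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]

    feature_names = None
    start = 0
    if header and lines:
        fields = lines[0].split(delimiter)
        lc = label_column if label_column >= 0 else len(fields) + label_column
        feature_names = [f for j, f in enumerate(fields) if j != lc]
        start = 1

    rows, raw, mapped = [], [], []
    n_fields = None
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in ln.split(delimiter)]
        if n_fields is None:
            n_fields = len(fields)
        elif len(fields) != n_fields:
            raise ParseError(
                f"line {lineno}: expected {n_fields} fields, found {len(fields)}"
            )
        if missing_token in fields:
            if missing_policy == "drop":
                continue
            raise ParseError(
                f"line {lineno}: missing value {missing_token!r} "
                "(set missing_policy='drop' to skip such rows)"
            )
        lc = label_column if label_column >= 0 else len(fields) + label_column
        raw_label = fields[lc]
        if raw_label not in label_map:
            raise ParseError(f"line {lineno}: unknown label value {raw_label!r}")
        try:
            feats = [float(f) for j, f in enumerate(fields) if j != lc]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric feature field ({exc})")
        rows.append(feats)
        raw.append(raw_label)
        mapped.append(label_map[raw_label])

    if not rows:
        raise ParseError(f"{path}: no data rows")
    return LabeledDataset(
        features=np.array(rows, dtype=float),
        labels=np.array(mapped, dtype=int),
        raw_labels=np.array(raw),
        feature_names=feature_names,
    )


def write_delimited(data: LabeledDataset, path, delimiter: str = ",") -> None:
    """Write a dataset in the same dialect ``read_delimited`` accepts.

    Features are written with ``repr`` precision so a read-back reproduces
    them to full double precision; the raw label goes in the last column.
    """
    with open(path, "w") as fh:
        for i in range(data.n_samples):
            fields = [repr(float(v)) for v in data.features[i]]
            fields.append(str(data.raw_labels[i]))
            fh.write(delimiter.join(fields) + "\n")


def normalize_minmax(train: LabeledDataset) -> tuple[LabeledDataset, NormalizationParams]:
    """Scale each feature to [0, 1] by its training-set range.

    Constant features map to 0.  The returned parameters are meant to be
    reapplied to held-out data with :func:`apply_normalization`; test
    values outside the training range land outside [0, 1] and are not
    clipped.
    """
    if train.n_samples == 0:
        raise ValueError("cannot normalize an empty dataset")
    mins = train.features.min(axis=0)
    maxs = train.features.max(axis=0)
    params = NormalizationParams(mins=mins, maxs=maxs)
    return apply_normalization(train, params), params


def apply_normalization(data: LabeledDataset, params: NormalizationParams) -> LabeledDataset:
    """Apply stored (min, max) scaling: (x - min) / (max - min).

    Not idempotent in general — applying train-fitted parameters twice
    rescales twice.  Degenerate ranges (max == min) map to 0.
    """
    if params.n_features != data.n_features:
        raise ValueError(
            f"normalization fitted on {params.n_features} features, "
            f"data has {data.n_features}"
        )
    span = params.maxs - params.mins
    scaled = np.where(span > 0, (data.features - params.mins) / np.where(span > 0, span, 1.0), 0.0)
    out = dataclasses.replace(data, features=scaled)
    out.normalization = params
    return out


def split(data: LabeledDataset, spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition into train/test sets of sizes (n_train, n - n_train).

    Stratified random by default; ``order="first-n"`` takes the first
    ``n_train`` rows in file order instead.  Deterministic under
    ``spec.seed``.
    """
    n = data.n_samples
    if spec.n_train >= n:
        raise ValueError(f"n_train={spec.n_train} must be < n_samples={n}")

    if spec.order == "first-n":
        train_idx = np.arange(spec.n_train)
        test_idx = np.arange(spec.n_train, n)
    elif spec.stratified:
        rng = np.random.default_rng(spec.seed)
        frac = spec.n_train / n
        parts = []
        for cls in (1, -1):
            cls_idx = np.flatnonzero(data.labels == cls)
            rng.shuffle(cls_idx)
            parts.append((cls_idx, int(round(len(cls_idx) * frac))))
        # fix rounding so the train side has exactly n_train rows
        total = sum(k for _, k in parts)
        if total != spec.n_train:
            idx0, k0 = parts[0]
            parts[0] = (idx0, k0 + (spec.n_train - total))
        train_idx = np.concatenate([idx[:k] for idx, k in parts])
        test_idx = np.concatenate([idx[k:] for idx, k in parts])
        train_idx.sort()
        test_idx.sort()
    else:
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(n)
        train_idx = np.sort(perm[: spec.n_train])
        test_idx = np.sort(perm[spec.n_train :])

    train, test = data.take(train_idx), data.take(test_idx)
    if spec.stratified and spec.order == "random":
        for part, name in ((train, "train"), (test, "test")):
            if len(np.unique(part.labels)) < 2:
                raise ValueError(f"stratified split left a single class in the {name} set")
    return train, test


def generate_synthetic(
    n_per_class: tuple[int, int] = (150, 120),
    n_features: int = 13,
    separation: float = 2.5,
    seed: int = 0,
    raw_encoding: tuple = (1, 2),
) -> LabeledDataset:
    """Two isotropic Gaussian clusters emulating a two-class clinical table.

    Class means sit ``separation`` apart along the diagonal direction
    (all-ones unit vector) with unit-variance noise per feature, so the
    Bayes error is ``Phi(-separation / 2)`` regardless of dimension.
    Raw labels follow the benign/malignant ``{1, 2}`` encoding (mapped to
    ``{+1, -1}``).  Defaults mirror the 270 x 13 heart-disease table's
    class sizes and dimension.

    Reproducible: a fixed ``seed`` yields a byte-identical matrix.
    """
    n_pos, n_neg = n_per_class
    if n_pos < 1 or n_neg < 1:
        raise ValueError("each class needs at least one sample")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    direction = np.ones(n_features) / np.sqrt(n_features)
    offset = 0.5 * separation * direction
    x_pos = rng.standard_normal((n_pos, n_features)) + offset
    x_neg = rng.standard_normal((n_neg, n_features)) - offset
    features = np.vstack([x_pos, x_neg])
    labels = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    raw = np.where(labels == 1, raw_encoding[0], raw_encoding[1])
    # shuffle rows so class blocks are interleaved like a real table dump
    perm = rng.permutation(n_pos + n_neg)
    return LabeledDataset(
        features=features[perm], labels=labels[perm], raw_labels=raw[perm]
    )
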