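"""Synthetic descriptor tables with planted, recorded ground truth.

The generator emulates the statistical shape of a PaDEL-style QSAR
descriptor matrix: a few hundred molecules against ~1500 descriptors of
which a large block is constant, a small planted subset is informative
for the class label, some descriptors are noisy copies of informative
ones (correlated blocks), and the rest are pure noise.  Class imbalance
is exact (e.g. 56 positives of 171), and label noise is applied as
count-preserving swaps so the printed imbalance stays exact.

Continuous descriptors are standard normal; a minority of the noise
descriptors are integer count-like draws, echoing the mix of real
descriptor families (autocorrelations vs. atom counts).  No chemistry is
simulated: the point is the structure the selection pipeline assumes,
with ground truth recorded so recovery is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .descriptor_io import DescriptorTable, LabeledDataset
from .feature_selection import FeatureSet

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "recovery_score",
    "toxicity_like_spec",
    "period_like_spec",
]

BOUNDARIES = ("axis_threshold", "xor_pair", "additive_threshold")

#: Fraction of pure-noise descriptors drawn as integer counts.
_COUNT_LIKE_FRACTION = 0.2
#: Class shift applied to informative descriptors outside the boundary score.
_CLASS_SHIFT = 1.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the synthetic descriptor generator."""

    n_molecules: int = 171
    n_features: int = 1538
    n_constant: int = 334
    n_informative: int = 8
    n_redundant: int = 20
    block_correlation: float = 0.9
    positive_fraction: float = 0.33
    boundary: str = "additive_threshold"
    label_noise: float = 0.0
    seed: int = 0
    positive_class_name: str = "positive"
    negative_class_name: str = "negative"

    def __post_init__(self) -> None:
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")
        if self.n_constant + self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("feature category counts exceed n_features")
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if self.boundary == "xor_pair" and self.n_informative < 2:
            raise ValueError("xor_pair boundary needs >= 2 informative features")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.n_positive == 0 or self.n_positive == self.n_molecules:
            raise ValueError("positive_fraction leaves a class empty")

    @property
    def n_positive(self) -> int:
        return round(self.positive_fraction * self.n_molecules)

    def with_(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


def toxicity_like_spec(**kw) -> SyntheticSpec:
    """Shape of the toxicity dataset: 171 molecules, 33% positive,
    1538 descriptors with 334 constant."""
    defaults = dict(
        n_molecules=171, n_features=1538, n_constant=334,
        positive_fraction=0.33, positive_class_name="toxic",
        negative_class_name="non-toxic",
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def period_like_spec(**kw) -> SyntheticSpec:
    """Shape of the circadian-period dataset: 90 molecules, 30% period
    lengtheners, 1538 descriptors with 360 constant."""
    defaults = dict(
        n_molecules=90, n_features=1538, n_constant=360,
        positive_fraction=0.30, positive_class_name="lengthener",
        negative_class_name="no-changer",
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring after selection."""

    informative_features: list[str]
    redundant_map: dict[str, str]
    constant_features: list[str]
    true_labels_preflip: list[str]
    noise_features: list[str] = field(default_factory=list)

    @property
    def signal_features(self) -> set[str]:
        return set(self.informative_features) | set(self.redundant_map)


def _feature_names(p: int) -> list[str]:
    width = max(4, len(str(p)))
    return [f"D{j + 1:0{width}d}" for j in range(p)]


def _molecule_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"M{i + 1:0{width}d}" for i in range(n)]


def _boundary_score(X_inf: np.ndarray, boundary: str) -> tuple[np.ndarray, set[int]]:
    """Score driving the labels, and which informative columns it uses."""
    if boundary == "axis_threshold":
        return X_inf[:, 0], {0}
    if boundary == "xor_pair":
        return X_inf[:, 0] * X_inf[:, 1], {0, 1}
    return X_inf.sum(axis=1), set(range(X_inf.shape[1]))


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Generate a labeled descriptor table per the spec.

    The label is a quantile cut on the boundary score (the top
    ``n_positive`` molecules are positive), so class counts are exact.
    Informative columns not contributing to the score receive a
    class-conditional mean shift instead.  Label noise swaps equally
    many positives and negatives (count-preserving).  The result is
    fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_molecules, spec.n_features
    names = _feature_names(p)
    ids = _molecule_ids(n)

    # assign category positions uniformly over the columns
    perm = rng.permutation(p)
    inf_idx = perm[: spec.n_informative]
    red_idx = perm[spec.n_informative: spec.n_informative + spec.n_redundant]
    const_idx = perm[
        spec.n_informative + spec.n_redundant:
        spec.n_informative + spec.n_redundant + spec.n_constant
    ]
    noise_idx = perm[spec.n_informative + spec.n_redundant + spec.n_constant:]

    X = np.empty((n, p), dtype=float)

    X_inf = rng.standard_normal((n, spec.n_informative))
    score, score_cols = _boundary_score(X_inf, spec.boundary)
    order = np.argsort(-score, kind="stable")
    y = np.zeros(n, dtype=int)
    y[order[: spec.n_positive]] = 1
    signed = 2 * y - 1
    for c in range(spec.n_informative):
        if c not in score_cols:
            X_inf[:, c] += _CLASS_SHIFT * signed
    X[:, inf_idx] = X_inf

    # correlated noisy copies of informative columns
    rho = spec.block_correlation
    jitter_sd = np.sqrt(1.0 / rho**2 - 1.0) if rho > 0 else 1.0
    redundant_map: dict[str, str] = {}
    for r, j in enumerate(red_idx):
        src = r % spec.n_informative
        X[:, j] = X_inf[:, src] + jitter_sd * rng.standard_normal(n)
        redundant_map[names[j]] = names[inf_idx[src]]

    X[:, const_idx] = rng.integers(0, 3, size=spec.n_constant).astype(float)

    n_counts = round(_COUNT_LIKE_FRACTION * len(noise_idx))
    count_cols = noise_idx[:n_counts]
    cont_cols = noise_idx[n_counts:]
    X[:, count_cols] = rng.poisson(3.0, size=(n, len(count_cols))).astype(float)
    X[:, cont_cols] = rng.standard_normal((n, len(cont_cols)))

    preflip = y.copy()
    if spec.label_noise > 0:
        n_swap = round(spec.label_noise * n / 2)
        n_swap = min(n_swap, spec.n_positive - 1, n - spec.n_positive - 1)
        if n_swap > 0:
            pos_pool = np.flatnonzero(y == 1)
            neg_pool = np.flatnonzero(y == 0)
            flip_pos = rng.choice(pos_pool, size=n_swap, replace=False)
            flip_neg = rng.choice(neg_pool, size=n_swap, replace=False)
            y[flip_pos] = 0
            y[flip_neg] = 1

    to_name = {1: spec.positive_class_name, 0: spec.negative_class_name}
    table = DescriptorTable(
        molecule_ids=ids,
        feature_names=names,
        values=X,
        source_note=f"synthetic descriptor table (seed={spec.seed})",
    )
    dataset = LabeledDataset(
        table=table,
        labels=[to_name[v] for v in y],
        positive_class_name=spec.positive_class_name,
        negative_class_name=spec.negative_class_name,
    )
    truth = GroundTruth(
        informative_features=[names[j] for j in inf_idx],
        redundant_map=redundant_map,
        constant_features=[names[j] for j in const_idx],
        true_labels_preflip=[to_name[v] for v in preflip],
        noise_features=[names[j] for j in noise_idx],
    )
    return dataset, truth


def recovery_score(
    selected: FeatureSet | Sequence[str], truth: GroundTruth
) -> float:
    """Fraction of selected descriptors that carry planted signal.

    A descriptor counts as recovered if it is informative or a redundant
    (correlated) copy of an informative one.  Empty selections score 0.
    """
    names = list(selected.names if isinstance(selected, FeatureSet) else selected)
    if not names:
        return 0.0
    signal = truth.signal_features
    return sum(1 for f in names if f in signal) / len(names)
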