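"""Synthetic proteomic-like matrices with known ground truth.

The generator emulates the structure of the panels the pipeline targets: a
small cohort (tens to low hundreds of samples), thousands of features, a
handful of truly informative markers, correlated redundant copies of each
(mimicking multiple aptamers that target the same protein and therefore
share a gene symbol), mild class imbalance, and Gaussian noise features.
It does NOT attempt realistic proteome-wide covariance or batch effects —
a clean testbed for selector/weighting behavior, not a serum simulator.

Classification: informative features get a between-class mean shift of
``effect_size`` (in noise-sd units). Regression: each informative feature
contributes slope ``effect_size`` to a Gaussian-noise target. Redundant
copies are generated as rho * x + sqrt(1 - rho^2) * noise, so they
correlate with their parent at ``redundancy_rho`` and carry an attenuated
copy of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_transforms import ExpressionMatrix, TargetVector


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults are the package's standard desk-scale
    scenario (cohort of 100, 1000 markers, 10 informative each with 2
    copies correlated at 0.8, 1.5-sd effect, 27:65 positive fraction)."""

    n_samples: int = 100
    n_features: int = 1000
    n_informative: int = 10
    n_redundant_per_informative: int = 2
    redundancy_rho: float = 0.8
    effect_size: float = 1.5
    class_ratio: float = 27 / 65
    noise_sd: float = 1.0
    unknown_fraction: float = 0.0
    task: str = "classification"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        if self.n_informative * (1 + self.n_redundant_per_informative) > self.n_features:
            raise ValueError("informative groups do not fit into n_features")
        if not (0 < self.class_ratio < 1):
            raise ValueError("class_ratio must be in (0, 1)")
        if not (0 <= self.unknown_fraction < 1):
            raise ValueError("unknown_fraction must be in [0, 1)")
        if not (0 < self.redundancy_rho < 1):
            raise ValueError("redundancy_rho must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_samples, self.n_features, self.n_informative) < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth: the planted informative feature IDs and, per planted
    feature, its redundancy group (itself plus its correlated copies)."""

    informative: list[str]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def group_recovered(self, selected) -> int:
        """Number of informative groups with at least one member selected."""
        sel = set(selected)
        return sum(1 for f in self.informative if sel & set(self.groups[f]))


def _feature_ids(p: int) -> list[str]:
    width = max(4, len(str(p)))
    return [f"F{j + 1:0{width}d}" for j in range(p)]


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, TargetVector, SyntheticTruth]:
    """Draw one matrix + target + ground truth, fully determined by the seed.

    Features are laid out as [informative block | redundant copies | noise]
    and then assigned IDs in that order. Informative features and their
    copies share a gene symbol (GENE1, GENE2, ...); noise features carry no
    symbol, exercising partial symbol coverage downstream.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    ninf, ncopy = spec.n_informative, spec.n_redundant_per_informative
    ids = _feature_ids(p)

    values = rng.normal(0.0, spec.noise_sd, size=(n, p))
    base = rng.normal(0.0, 1.0, size=(n, ninf))  # informative cores, unit sd
    values[:, :ninf] = base
    for c in range(ncopy):
        cols = slice(ninf * (1 + c), ninf * (2 + c))
        noise = rng.normal(0.0, 1.0, size=(n, ninf))
        values[:, cols] = (
            spec.redundancy_rho * base
            + np.sqrt(1 - spec.redundancy_rho**2) * noise
        )

    if spec.task == "classification":
        n_pos = int(round(spec.class_ratio * n))
        n_pos = min(max(n_pos, 1), n - 1)
        codes = np.zeros(n, dtype=int)
        codes[rng.permutation(n)[:n_pos]] = 1
        # plant the class shift on the cores; copies inherit rho * shift
        shift = spec.effect_size * codes[:, None]
        values[:, :ninf] += shift
        for c in range(ncopy):
            cols = slice(ninf * (1 + c), ninf * (2 + c))
            values[:, cols] += spec.redundancy_rho * shift
        labels = np.where(codes == 1, "methylated", "unmethylated")
        unknown = np.zeros(n, dtype=bool)
        if spec.unknown_fraction > 0:
            n_unknown = int(round(spec.unknown_fraction * n))
            unknown[rng.permutation(n)[:n_unknown]] = True
            labels = labels.astype(object)
            labels[unknown] = "unknown"
        target = TargetVector("binary", labels, "methylated", unknown)
    else:
        y = spec.effect_size * base.sum(axis=1) + rng.normal(0.0, spec.noise_sd, n)
        unknown = np.zeros(n, dtype=bool)
        if spec.unknown_fraction > 0:
            n_unknown = int(round(spec.unknown_fraction * n))
            unknown[rng.permutation(n)[:n_unknown]] = True
        target = TargetVector("continuous", y, unknown_mask=unknown)

    symbols: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for i in range(ninf):
        members = [ids[i]] + [ids[ninf * (1 + c) + i] for c in range(ncopy)]
        groups[ids[i]] = members
        for m in members:
            symbols[m] = f"GENE{i + 1}"

    matrix = ExpressionMatrix(
        [f"S{i + 1:03d}" for i in range(n)], ids, values, symbols
    )
    truth = SyntheticTruth(informative=ids[:ninf], groups=groups)
    return matrix, target, truth


def rfu_like(matrix: ExpressionMatrix, offset: float = 10.0) -> ExpressionMatrix:
    """Map values onto a positive RFU-like intensity scale: v -> 2**(v + offset).

    log2_transform inverts this up to the additive offset, so the log2
    preprocessing preset can be exercised end to end on synthetic data.
    """
    from dataclasses import replace

    return replace(matrix, values=np.exp2(matrix.values + offset))
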