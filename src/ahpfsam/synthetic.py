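"""Synthetic two-class expression matrices with known informative genes.

Emulates the high-dimensional-low-sample microarray regime: a Gaussian
null background of uninformative genes plus a small block of informative
genes whose class means differ by a controlled effect size. Ground truth
is returned alongside the dataset so selection and classification can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionDataset

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    effect_size is the between-class mean shift in units of the
    within-class standard deviation (noise_sd); informative shifts
    alternate sign across genes so direction-free scoring is exercised.
    An optional equicorrelation couples the informative block; an optional
    contamination fraction replaces samples with 5-sd heavy-tailed draws
    to exercise the rank-based criteria.
    """

    n_genes: int = 200
    n_samples: int = 60
    n_informative: int = 5
    effect_size: float = 3.0
    class_balance: float = 0.5
    noise_sd: float = 1.0
    correlation: float = 0.0
    contamination: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must be in [0, 1)")


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, list[str]]:
    """Draw one dataset; returns (dataset, informative gene ids).

    Labels: the first ceil(balance * n) samples are class 0, the rest
    class 1 (column order carries no information for any of the methods).
    Informative genes are the first n_informative rows; gene IDs are
    G0001, G0002, ... so the truth list is human-readable.
    """
    rng = np.random.default_rng(spec.seed)
    n0 = int(np.ceil(spec.class_balance * spec.n_samples))
    n1 = spec.n_samples - n0
    if n0 < 2 or n1 < 2:
        raise ValueError("class balance leaves a class with <2 samples")
    labels = np.array([0] * n0 + [1] * n1)

    x = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))

    if spec.correlation > 0 and spec.n_informative > 1:
        # equicorrelated block via a shared factor per sample
        rho = spec.correlation
        shared = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        block = np.sqrt(rho) * shared + np.sqrt(1 - rho) * x[: spec.n_informative]
        x[: spec.n_informative] = block

    shift = spec.effect_size * spec.noise_sd
    for g in range(spec.n_informative):
        sign = 1.0 if g % 2 == 0 else -1.0
        x[g, labels == 1] += sign * shift

    if spec.contamination > 0:
        mask = rng.random(size=x.shape) < spec.contamination
        x = np.where(mask, rng.normal(0.0, 5 * spec.noise_sd, size=x.shape), x)

    width = len(str(spec.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j + 1:03d}" for j in range(spec.n_samples)]
    ds = ExpressionDataset(x, gene_ids, sample_ids, labels,
                           label_mapping={"0": 0, "1": 1})
    return ds, gene_ids[: spec.n_informative]
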