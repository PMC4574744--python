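"""Synthetic expression, screen and platform data with planted ratio structure.

The generator emulates the structure of a pharmacogenomic screen panel: a
positive-valued expression matrix on a MAS5-like linear scale (baseline
around 150), binary sensitivity labels at a configurable prevalence
(default 23%), and a small set of planted "true" gene-pair ratios whose
class-conditional mean log-ratio differs between sensitive and insensitive
samples.

Planting mechanism: each planted pair (up, down) is reciprocally regulated —
a per-sample latent factor enters the numerator positively and the
denominator negatively (the anti-correlated expression motif of a regulator
buffering its target), and sensitive samples additionally shift the
numerator up and the denominator down by half the class effect each.  The
planted log-ratio therefore concentrates both the latent-factor variance and
the class effect, making it the natural exemplar of the cluster of ratios
that share its genes, while the global per-sample scale factor cancels in
every ratio but contaminates every single-gene feature.  This makes "ratios
beat single genes under scale confounding" a designed, testable property.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .screens import SENSITIVE, DoseResponse, sigmoid_inhibition

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_expression",
    "generate_platform_replica",
    "generate_screens",
    "default_dose_grid",
]

#: 11-point 2.5-fold dilution series from 20 nM down to ~2.1 pM, ascending.
def default_dose_grid() -> np.ndarray:
    return 20e-9 / 2.5 ** np.arange(10, -1, -1)


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of the simulated screen-plus-expression study.

    effect_size is the class difference in mean log-ratio of each planted
    pair, in units of noise_sd; noise_sd is the per-gene log-scale noise;
    pair_cofactor_sd scales the latent factor that anti-correlates a planted
    pair (in units of noise_sd); per_sample_scale_range bounds the log-uniform
    multiplicative factor applied to all genes of a sample (platform/batch
    effect); baseline is the linear-scale expression location.
    """

    n_samples: int = 400
    n_genes: int = 200
    hypothesis_set_size: int = 60
    n_true_ratios: int = 5
    effect_size: float = 2.0
    prevalence: float = 0.23
    noise_sd: float = 0.5
    baseline: float = 150.0
    gene_location_mu: float = 1.3  # log offset of gene locations above baseline
    gene_location_sd: float = 1.0
    pair_cofactor_sd: float = 0.6
    planted_location_mu: float = 2.0  # log offset above baseline for signal genes
    planted_location_sd: float = 0.3
    per_sample_scale_range: tuple[float, float] = (0.5, 2.0)
    signal: str = "ratio"  # "ratio" | "single_gene" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.hypothesis_set_size) <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        lo, hi = self.per_sample_scale_range
        if not (0 < lo <= hi):
            raise ValueError("per_sample_scale_range must be positive and ordered")
        if self.signal not in ("ratio", "single_gene", "none"):
            raise ValueError(f"unknown signal mode: {self.signal!r}")
        if self.signal == "ratio" and 2 * self.n_true_ratios > self.hypothesis_set_size:
            raise ValueError("planted ratios exceed available hypothesis gene pairs")
        if self.hypothesis_set_size > self.n_genes:
            raise ValueError("hypothesis set larger than the gene universe")


@dataclass
class SyntheticDataset:
    X: pd.DataFrame  # genes x samples, positive linear scale
    labels: np.ndarray  # 1 = sensitive
    hypothesis_genes: list[str]
    true_ratios: list[tuple[str, str]]  # (numerator up in sensitives, denominator)
    config: SyntheticConfig
    scale_factors: np.ndarray = field(default_factory=lambda: np.array([]))


def _pair_cofactor_sd(cfg: SyntheticConfig) -> float:
    return cfg.pair_cofactor_sd * cfg.noise_sd


def generate_expression(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic expression matrix with labels and planted truth."""
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes
    labels = (rng.random(n) < cfg.prevalence).astype(int)
    # guarantee both classes exist so downstream statistics are defined
    if labels.sum() < 2:
        labels[:2] = 1
    if (1 - labels).sum() < 2:
        labels[:2] = 0

    gene_ids = [f"G{i:04d}" for i in range(g)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    mu = np.log(cfg.baseline) + rng.normal(
        cfg.gene_location_mu, cfg.gene_location_sd, size=g
    )
    # signal-carrying genes are modeled as clearly expressed: a gene near the
    # array noise floor cannot carry a measurable ratio signal, and the
    # expression/IQR filters would (correctly) remove it
    n_signal = 2 * cfg.n_true_ratios if cfg.signal == "ratio" else (
        1 if cfg.signal == "single_gene" else 0
    )
    if n_signal:
        mu[:n_signal] = np.log(cfg.baseline) + rng.normal(
            cfg.planted_location_mu, cfg.planted_location_sd, size=n_signal
        )
    logx = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(g, n))

    delta = cfg.effect_size * cfg.noise_sd
    true_ratios: list[tuple[str, str]] = []
    if cfg.signal == "ratio":
        f_sd = _pair_cofactor_sd(cfg)
        for k in range(cfg.n_true_ratios):
            up, dn = 2 * k, 2 * k + 1
            cofactor = rng.normal(0.0, f_sd, size=n)
            logx[up] += cofactor + 0.5 * delta * labels
            logx[dn] += -cofactor - 0.5 * delta * labels
            true_ratios.append((gene_ids[up], gene_ids[dn]))
    elif cfg.signal == "single_gene":
        logx[0] += delta * labels
        true_ratios = []

    lo, hi = cfg.per_sample_scale_range
    log_scale = rng.uniform(np.log(lo), np.log(hi), size=n)
    logx += log_scale[None, :]

    X = pd.DataFrame(np.exp(logx), index=gene_ids, columns=sample_ids)
    extra = rng.choice(
        np.arange(n_signal, g), size=cfg.hypothesis_set_size - n_signal, replace=False
    )
    hypothesis = gene_ids[:n_signal] + [gene_ids[i] for i in sorted(extra)]
    return SyntheticDataset(
        X=X,
        labels=labels,
        hypothesis_genes=hypothesis,
        true_ratios=true_ratios,
        config=cfg,
        scale_factors=np.exp(log_scale),
    )


def generate_platform_replica(
    X: pd.DataFrame,
    per_sample_scale_range: tuple[float, float] = (0.5, 2.0),
    per_gene_shift_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """A platform-shifted replica X'[g,s] = X[g,s] * alpha_s * beta_g.

    alpha_s is log-uniform over the per-sample range; beta_g is log-normal
    with the given log-scale sd, emulating probe-efficiency differences
    between platforms.  Used to test prediction stability with no rescaling.
    """
    lo, hi = per_sample_scale_range
    if not (0 < lo <= hi) or per_gene_shift_sd < 0:
        raise ValueError("scale parameters must be positive")
    rng = np.random.default_rng(seed)
    alpha = np.exp(rng.uniform(np.log(lo), np.log(hi), size=X.shape[1]))
    beta = np.exp(rng.normal(0.0, per_gene_shift_sd, size=X.shape[0]))
    return X * np.outer(beta, alpha)


def generate_screens(
    labels: Sequence,
    n_screens: int = 3,
    concordance_noise: float = 0.0,
    dose_grid: np.ndarray | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    cell_line_ids: Sequence[str] | None = None,
) -> list[DoseResponse]:
    """Dose-response curves for each line in each screen, consistent with labels.

    Sensitive lines draw Amax from [75, 95], insensitive from [10, 45]; with
    probability ``concordance_noise`` a screen instead draws from the other
    class's band, flipping that screen's call.  EC50 is log-uniform inside
    the middle of the dose grid and curves are noiseless sigmoids, so with
    ``concordance_noise=0`` consensus calls round-trip the labels exactly.
    ``missing_rate`` drops (line, screen) combinations at random, keeping at
    least one screen per line.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == SENSITIVE).astype(int)
    y = y.astype(int)
    if dose_grid is None:
        dose_grid = default_dose_grid()
    dose_grid = np.asarray(dose_grid, dtype=float)
    if np.any(np.diff(dose_grid) <= 0):
        raise ValueError("dose grid must be ascending")
    rng = np.random.default_rng(seed)
    if cell_line_ids is None:
        cell_line_ids = [f"S{i:04d}" for i in range(y.size)]
    lo_d, hi_d = dose_grid[1], dose_grid[-2]
    curves: list[DoseResponse] = []
    for i, line in enumerate(cell_line_ids):
        present = rng.random(n_screens) >= missing_rate
        if not present.any():
            present[rng.integers(n_screens)] = True
        for s in range(n_screens):
            if not present[s]:
                continue
            flip = rng.random() < concordance_noise
            effective = y[i] ^ int(flip)
            a_max = rng.uniform(75.0, 95.0) if effective else rng.uniform(10.0, 45.0)
            ec50 = np.exp(rng.uniform(np.log(lo_d), np.log(hi_d)))
            inhibition = sigmoid_inhibition(dose_grid, a_max, ec50, hill=1.0)
            curves.append(
                DoseResponse(
                    cell_line_id=str(line),
                    screen_id=f"screen{s}",
                    doses=dose_grid.copy(),
                    inhibition=inhibition,
                )
            )
    return curves
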