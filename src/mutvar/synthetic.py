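"""Synthetic inputs with the statistical structure the analyses assume.

Generates the three kinds of input the pipeline consumes, so every
downstream stage is testable without the external genome track or the
published DNM/SNP sets:

* an MI *site track* — how many genomic sites carry each integer
  mutability-index value (a discretized Gaussian mixture standing in
  for the genome-wide MI distribution, whose true shape is not public);
* *de novo mutation* datasets — per-site counts Poisson-sampled from a
  log-linear rate ``base**(a + b*MI)``, optionally with mean-one
  lognormal cryptic rate variation per site and an MI-dependent
  under-reporting bias (emulating ascertainment loss in the more
  mutable regions);
* two-species SNP tables in which coincidence is drawn directly from
  the per-site kernel probability ``u_a*u_b*K(gamma)`` under mean-one
  gamma rates — the Monte-Carlo realization of the coincident-SNP
  theory, used as its independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .coincident import kernel

__all__ = [
    "MISiteTrack",
    "TrueRateModel",
    "DNMDataset",
    "TwoSpeciesSNPTable",
    "mean_one_lognormal",
    "make_mi_track",
    "sample_dnms",
    "sample_coincident_snps",
    "empirical_excess",
]


@dataclass(frozen=True)
class MISiteTrack:
    """Per-MI site counts: how many genomic sites have each MI value."""

    mi: np.ndarray        # integer MI values, unique
    n_sites: np.ndarray   # non-negative site counts, same length

    def __post_init__(self):
        mi = np.asarray(self.mi, dtype=int)
        n = np.asarray(self.n_sites, dtype=np.int64)
        if mi.shape != n.shape or mi.ndim != 1:
            raise ValueError("mi and n_sites must be 1-D arrays of equal length")
        if len(np.unique(mi)) != len(mi):
            raise ValueError("MI values must be unique within a track")
        if (n < 0).any():
            raise ValueError("site counts must be non-negative")
        if n.sum() <= 0:
            raise ValueError("track must contain at least one site")
        object.__setattr__(self, "mi", mi)
        object.__setattr__(self, "n_sites", n)

    @property
    def total_sites(self) -> int:
        return int(self.n_sites.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mi": self.mi, "n_sites": self.n_sites})


@dataclass(frozen=True)
class TrueRateModel:
    """Generating model: per-site rate ``base**(a + b*mi)`` times a
    mean-one lognormal factor with variance ``cryptic_variance``."""

    intercept: float
    slope: float
    log_base: float = 10.0
    cryptic_variance: float = 0.0

    def __post_init__(self):
        if self.cryptic_variance < 0:
            raise ValueError("cryptic_variance must be >= 0")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")

    def rate(self, mi) -> np.ndarray:
        return np.power(self.log_base, self.intercept + self.slope * np.asarray(mi, dtype=float))


@dataclass(frozen=True)
class DNMDataset:
    """De novo mutations: one row per DNM (chrom, pos, mi, study)."""

    frame: pd.DataFrame

    REQUIRED = ("chrom", "pos", "mi", "study")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"DNM table missing column(s): {', '.join(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def mi(self) -> np.ndarray:
        return self.frame["mi"].to_numpy()


@dataclass(frozen=True)
class TwoSpeciesSNPTable:
    """Per-site SNP status in two species.

    Columns: site_id, is_cpg, snp_a, snp_b, plus (synthetic tables only)
    the true rate multiplier gamma_true and optionally an MI value.
    """

    frame: pd.DataFrame

    REQUIRED = ("site_id", "is_cpg", "snp_a", "snp_b")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"SNP table missing column(s): {', '.join(missing)}")
        if "gamma_true" in self.frame.columns:
            g = self.frame["gamma_true"].dropna()
            if (g <= 0).any():
                raise ValueError("gamma_true must be positive where present")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def coincident(self) -> np.ndarray:
        f = self.frame
        return (f["snp_a"].to_numpy().astype(bool)
                & f["snp_b"].to_numpy().astype(bool))


def mean_one_lognormal(
    variance: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Draw mean-one lognormal factors with the given variance.

    The unique lognormal with mean 1 and variance ``V`` has log-scale
    ``sigma**2 = ln(1 + V)`` and log-mean ``-sigma**2 / 2``.  ``V = 0``
    returns exact ones (no draws consumed).
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return np.ones(size)
    sigma2 = np.log1p(variance)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def make_mi_track(
    n_total: int,
    mixture_spec: Sequence[Tuple[float, float, float]],
    mi_range: Tuple[int, int],
    seed: Optional[int] = None,
) -> MISiteTrack:
    """Draw a genome-like MI site track from a discretized Gaussian mixture.

    Each component ``(weight, mean_mi, sd_mi)`` contributes probability
    mass at integer MI values via CDF differences on ``[m-0.5, m+0.5]``;
    the mixture is truncated to ``mi_range`` (inclusive), renormalized,
    and ``n_total`` sites are allocated by a single multinomial draw, so
    the total is exactly ``n_total``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be a positive integer")
    if not mixture_spec:
        raise ValueError("mixture_spec must contain at least one component")
    lo, hi = int(mi_range[0]), int(mi_range[1])
    if hi < lo:
        raise ValueError(f"empty mi_range {mi_range}")
    weights = np.array([w for w, _, _ in mixture_spec], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError(f"mixture weights must sum to 1, got {weights.sum()}")

    grid = np.arange(lo, hi + 1)
    pmf = np.zeros(grid.size)
    for w, mu, sd in mixture_spec:
        if sd <= 0:
            raise ValueError("component sd must be positive")
        upper = stats.norm.cdf(grid + 0.5, loc=mu, scale=sd)
        lower = stats.norm.cdf(grid - 0.5, loc=mu, scale=sd)
        pmf += w * (upper - lower)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("mixture has no mass inside mi_range")
    pmf /= total

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_total, pmf)
    keep = counts > 0
    return MISiteTrack(mi=grid[keep], n_sites=counts[keep])


def sample_dnms(
    track: MISiteTrack,
    model: TrueRateModel,
    n_dnm_target: int,
    reporting_bias: Optional[Callable[[int], float]] = None,
    seed: Optional[int] = None,
    study: str = "synthetic",
) -> DNMDataset:
    """Poisson-sample a DNM dataset from the track under the rate model.

    Rates are rescaled so the expected total DNM count equals
    ``n_dnm_target``.  When the model carries cryptic variance, each
    site receives its own mean-one lognormal factor before Poisson
    sampling, producing overdispersion ``Var = m + m**2 * V`` at a
    single site.  ``reporting_bias(mi) -> retention probability``
    thins records after sampling, emulating MI-dependent
    under-ascertainment.
    """
    if n_dnm_target <= 0:
        raise ValueError("n_dnm_target must be positive")
    rng = np.random.default_rng(seed)
    rates = model.rate(track.mi)
    scale = n_dnm_target / float(np.dot(track.n_sites, rates))

    rows_mi, rows_pos = [], []
    pos_offset = 0
    for mi, n, rate in zip(track.mi, track.n_sites, rates):
        lam = scale * rate
        if model.cryptic_variance > 0:
            factors = mean_one_lognormal(model.cryptic_variance, int(n), rng)
            mean_total = lam * factors.sum()
        else:
            mean_total = lam * n
        d = int(rng.poisson(mean_total))
        if reporting_bias is not None:
            p = float(reporting_bias(int(mi)))
            if p < 0 or p > 1:
                raise ValueError(
                    f"retention probability must be in [0, 1], got {p} at MI {mi}"
                )
            d = int(rng.binomial(d, p))
        rows_mi.append(np.full(d, mi, dtype=int))
        rows_pos.append(pos_offset + 1 + np.arange(d, dtype=np.int64))
        pos_offset += int(n)

    mi_col = np.concatenate(rows_mi) if rows_mi else np.array([], dtype=int)
    pos_col = np.concatenate(rows_pos) if rows_pos else np.array([], dtype=np.int64)
    frame = pd.DataFrame(
        {
            "chrom": np.full(mi_col.size, "chr1", dtype=object),
            "pos": pos_col,
            "mi": mi_col,
            "study": np.full(mi_col.size, study, dtype=object),
        }
    )
    return DNMDataset(frame)


def sample_coincident_snps(
    n_sites: int,
    shape: float,
    v: float,
    u_a: float,
    u_b: float,
    seed: Optional[int] = None,
    is_cpg: bool = False,
) -> TwoSpeciesSNPTable:
    """Monte-Carlo realization of the coincident-SNP probability model.

    Draws ``gamma`` per site from the mean-one gamma distribution and
    marks the site coincident with probability ``u_a*u_b*K(gamma, v)``
    where ``K`` is the coincidence kernel — i.e. it samples the model's
    own kernel, which is the faithful check of the quadrature theory.
    Sites that are not coincident receive single-species SNP flags by a
    simplistic ``u * gamma`` thinning so the table resembles a real
    two-species table; only the coincidence probability carries the
    model.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if shape <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if not (0.0 < v < 1.0):
        raise ValueError(f"divergence must lie in (0, 1), got {v}")
    if u_a < 0 or u_b < 0:
        raise ValueError("SNP densities must be non-negative")
    rng = np.random.default_rng(seed)
    gamma = rng.gamma(shape, scale=1.0 / shape, size=n_sites)
    p_coinc = np.clip(u_a * u_b * kernel(gamma, v), 0.0, 1.0)
    coincident = rng.random(n_sites) < p_coinc

    # single-species SNPs on the remaining sites, mutually exclusive so
    # the accidental overlap cannot contaminate the coincident class
    snp_a = coincident.copy()
    snp_b = coincident.copy()
    free = ~coincident
    p_a = np.clip(u_a * gamma[free], 0.0, 1.0)
    p_b = np.clip(u_b * gamma[free], 0.0, 1.0 - p_a)
    r = rng.random(free.sum())
    snp_a[free] = r < p_a
    snp_b[free] = (r >= p_a) & (r < p_a + p_b)

    frame = pd.DataFrame(
        {
            "site_id": np.arange(1, n_sites + 1, dtype=np.int64),
            "is_cpg": np.full(n_sites, bool(is_cpg)),
            "snp_a": snp_a,
            "snp_b": snp_b,
            "gamma_true": gamma,
        }
    )
    return TwoSpeciesSNPTable(frame)


def empirical_excess(
    table: TwoSpeciesSNPTable, u_a: float, u_b: float, v: float
) -> float:
    """Observed coincident-SNP excess ratio of a (synthetic) table.

    Coincident fraction divided by the uniform-rate expectation
    ``u_a * u_b * K(1, v)`` — the quantity ``fit_shape`` inverts.
    """
    frac = table.coincident.mean()
    return float(frac / (u_a * u_b * kernel(1.0, v)))
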