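"""Synthetic forest-inventory data with a chosen causal regime.

Real inventories behind this kind of analysis are mostly restricted, so the
generator produces plot-level data carrying the statistical structure the
per-region models assume: an elevation gradient driving mean tree size,
richness and abundance; a negative size→abundance path (Yoda's law
self-thinning); and a directional richness↔abundance link whose direction
is set by the regime (MSH: richness→abundance, MIH: abundance→richness,
NULL: no link).

Construction is latent-Gaussian-then-round: log richness and log abundance
are generated as linear-Gaussian responses, then materialized as counts via
``max(1, round(exp(latent)))``, so the fitted linear models on the observed
logs are approximately correctly specified.  Because the latent scheme does
not itself guarantee richness ≤ abundance, richness is capped at abundance
per plot and the cap rate is reported (negligible under the defaults).

``direction_effect`` is the *standardized* strength of the cross path; the
raw coefficient is derived from the scenario's population variances so that
the implied standardized path equals the requested value.

Cross-region inputs for the meta-analysis are generated analogously:
latitude drives productivity downward, ΔBIC responds to standardized
productivity with a chosen true effect, and latitude acts on ΔBIC only
through productivity and richness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .direction import MIH, MSH, NULL
from .plot_data import PlotRecord, RegionDataset, log_transform

__all__ = [
    "RegionScenario",
    "MetaScenario",
    "SimulatedRegionDataset",
    "simulate_region",
    "simulate_meta",
    "cross_path_coefficient",
]


@dataclass(frozen=True)
class RegionScenario:
    """Generative settings for one synthetic forest region.

    Defaults describe a mid-size mountain inventory: plots spread over a
    1500 m elevation gradient, mean tree size shrinking with elevation,
    ~12 species and ~70 stems per plot at the gradient base, and a clearly
    detectable directional link (standardized strength 0.6).
    """

    regime: str = MSH
    n_plots: int = 500
    seed: int = 0
    region_code: str = "SIM"
    elevation_range: tuple[float, float] = (0.0, 1500.0)  # m
    # mean tree size D (cm): D = d_intercept + size_elevation_slope * E + noise
    d_intercept: float = 30.0
    size_elevation_slope: float = -0.008  # cm per m elevation
    noise_sd_d: float = 4.0
    # log richness: s_intercept + env_effect_s * E (+ cross path under MIH)
    s_intercept: float = 2.5
    env_effect_s: float = -0.0006  # per m
    noise_sd_s: float = 0.35
    # log abundance: a_intercept + yoda_slope * D + env_effect_a * E (+ cross path under MSH)
    a_intercept: float = 5.5
    yoda_slope: float = -0.04  # per cm of mean DBH; must be negative
    env_effect_a: float = -0.0002  # per m
    noise_sd_a: float = 0.30
    # directional link strength, standardized scale
    direction_effect: float = 0.6
    # optional spatial clustering (inventory tracks): random intercepts on both logs
    n_clusters: int = 0
    cluster_sd: float = 0.0
    plot_size: float = 1000.0  # m²

    def __post_init__(self):
        if self.regime not in (MSH, MIH, NULL):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == NULL and self.direction_effect != 0.0:
            object.__setattr__(self, "direction_effect", 0.0)
        if not (self.yoda_slope < 0):
            raise ValueError("yoda_slope must be negative (self-thinning)")
        if min(self.noise_sd_d, self.noise_sd_s, self.noise_sd_a) <= 0:
            raise ValueError("noise_sd values must be positive")
        if not (-1.0 < self.direction_effect < 1.0):
            raise ValueError("direction_effect must lie in (-1, 1)")
        if self.n_plots < 3:
            raise ValueError("n_plots must be >= 3")
        if self.n_clusters < 0 or self.cluster_sd < 0:
            raise ValueError("cluster settings must be non-negative")
        lo, hi = self.elevation_range
        if not (hi > lo):
            raise ValueError("elevation_range must be increasing")


def _population_moments(sc: RegionScenario) -> dict[str, float]:
    """Population variances/covariances of the latent equations."""
    lo, hi = sc.elevation_range
    var_e = (hi - lo) ** 2 / 12.0
    cluster_var = sc.cluster_sd**2 if sc.n_clusters > 0 else 0.0
    cov_de = sc.size_elevation_slope * var_e
    var_d = sc.size_elevation_slope**2 * var_e + sc.noise_sd_d**2
    # logS without the cross path
    var_s0 = sc.env_effect_s**2 * var_e + sc.noise_sd_s**2 + cluster_var
    # logA without the cross path
    var_a0 = (
        sc.yoda_slope**2 * var_d
        + sc.env_effect_a**2 * var_e
        + 2.0 * sc.yoda_slope * sc.env_effect_a * cov_de
        + sc.noise_sd_a**2
        + cluster_var
    )
    # covariance between the two latents' non-cross parts (shared E gradient)
    cov_sa0 = sc.env_effect_s * var_e * (sc.env_effect_a + sc.yoda_slope * sc.size_elevation_slope)
    return {"var_e": var_e, "var_d": var_d, "var_s0": var_s0, "var_a0": var_a0, "cov_sa0": cov_sa0}


def cross_path_coefficient(sc: RegionScenario) -> float:
    """Raw coefficient of the cross path implied by the standardized strength.

    For a downstream variable Y = beta * U + rest, the standardized path is
    beta * sd(U) / sd(Y) with sd(Y) depending on beta; solving for beta with
    the scenario's population variances (and the U–rest covariance induced
    by the shared elevation gradient) gives the raw slope used in
    generation.
    """
    t = sc.direction_effect
    if t == 0.0:
        return 0.0
    m = _population_moments(sc)
    if sc.regime == MSH:
        var_u, var_rest = m["var_s0"], m["var_a0"]
    else:  # MIH
        var_u, var_rest = m["var_a0"], m["var_s0"]
    c = m["cov_sa0"]
    # beta^2 var_u (1 - t^2) - 2 t^2 c beta - t^2 var_rest = 0
    disc = t**2 * c**2 + var_u * var_rest * (1.0 - t**2)
    beta = (t**2 * c + abs(t) * math.sqrt(disc)) / (var_u * (1.0 - t**2))
    return math.copysign(beta, t)


class SimulatedRegionDataset(RegionDataset):
    """A RegionDataset plus the generator's latent values and cap rate."""

    def __init__(self, *args, latent: pd.DataFrame, cap_rate: float, **kwargs):
        super().__init__(*args, **kwargs)
        self.latent = latent
        self.cap_rate = cap_rate


def simulate_region(scenario: RegionScenario) -> SimulatedRegionDataset:
    """Draw one synthetic region under the scenario's causal regime.

    Independent random sub-streams are used per equation (elevation, size,
    richness noise, abundance noise, cluster intercepts) so switching the
    clustering on or off leaves the other draws untouched; a fixed seed
    yields identical output.
    """
    sc = scenario
    streams = np.random.SeedSequence(sc.seed).spawn(5)
    rng_e, rng_d, rng_s, rng_a, rng_c = (np.random.default_rng(s) for s in streams)
    n = sc.n_plots
    lo, hi = sc.elevation_range

    e = rng_e.uniform(lo, hi, size=n)
    d = sc.d_intercept + sc.size_elevation_slope * e + rng_d.normal(0.0, sc.noise_sd_d, size=n)
    nonpos = int((d <= 0).sum())
    if nonpos > 0.10 * n:
        raise ValueError(
            f"{nonpos}/{n} draws of mean tree size were non-positive; "
            "rescale d_intercept / size_elevation_slope / noise_sd_d"
        )
    d = np.clip(d, 0.5, None)

    if sc.n_clusters > 0:
        cluster_idx = np.arange(n) % sc.n_clusters
        cluster_ids = np.array([f"c{i:03d}" for i in cluster_idx])
        u_s = rng_c.normal(0.0, sc.cluster_sd, size=sc.n_clusters)[cluster_idx]
        u_a = rng_c.normal(0.0, sc.cluster_sd, size=sc.n_clusters)[cluster_idx]
    else:
        cluster_ids = None
        u_s = u_a = np.zeros(n)

    eps_s = rng_s.normal(0.0, sc.noise_sd_s, size=n)
    eps_a = rng_a.normal(0.0, sc.noise_sd_a, size=n)
    beta = cross_path_coefficient(sc)
    mean_e = 0.5 * (lo + hi)
    mean_d = sc.d_intercept + sc.size_elevation_slope * mean_e

    log_s0 = sc.s_intercept + sc.env_effect_s * e + u_s + eps_s
    log_a0 = sc.a_intercept + sc.yoda_slope * d + sc.env_effect_a * e + u_a + eps_a
    mean_s0 = sc.s_intercept + sc.env_effect_s * mean_e
    mean_a0 = sc.a_intercept + sc.yoda_slope * mean_d + sc.env_effect_a * mean_e

    if sc.regime == MSH:
        log_s = log_s0
        log_a = log_a0 + beta * (log_s0 - mean_s0)  # centred so mean abundance is stable
    elif sc.regime == MIH:
        log_a = log_a0
        log_s = log_s0 + beta * (log_a0 - mean_a0)
    else:
        log_s, log_a = log_s0, log_a0

    s_count = np.maximum(1, np.rint(np.exp(log_s))).astype(int)
    a_count = np.maximum(1, np.rint(np.exp(log_a))).astype(int)
    capped = s_count > a_count
    s_count = np.minimum(s_count, a_count)
    cap_rate = float(capped.mean())

    plots = [
        PlotRecord(
            plot_id=f"p{i:05d}",
            region_code=sc.region_code,
            cluster_id=None if cluster_ids is None else str(cluster_ids[i]),
            elevation=float(e[i]),
            richness=int(s_count[i]),
            abundance=int(a_count[i]),
            mean_dbh=float(d[i]),
        )
        for i in range(n)
    ]
    log_transform(plots)
    latent = pd.DataFrame(
        {"elevation": e, "mean_dbh": d, "log_richness_latent": log_s, "log_abundance_latent": log_a}
    )
    return SimulatedRegionDataset(
        region_code=sc.region_code,
        plots=plots,
        plot_size=sc.plot_size,
        latent=latent,
        cap_rate=cap_rate,
    )


# ---------------------------------------------------------------------------
# cross-region (meta) inputs


@dataclass(frozen=True)
class MetaScenario:
    """Generative settings for region-level records feeding the meta-SEM.

    ΔBIC is built on the standardized scale: the true productivity effect is
    the coefficient on z-scored NPP, richness contributes a (small) true
    confounding path, and latitude influences ΔBIC only through NPP and
    richness — so the latitude missing-path claim holds by construction.
    """

    n_regions: int = 23
    seed: int = 0
    npp_effect: float = -0.46  # true standardized NPP→ΔBIC path
    richness_effect: float = 0.1  # true standardized richness→ΔBIC path
    latitude_range: tuple[float, float] = (0.0, 70.0)  # degrees absolute
    npp_intercept: float = 2800.0  # gDM/m²/yr at the equator
    latitude_npp_slope: float = -35.0  # gDM/m²/yr per degree; negative
    npp_noise_sd: float = 200.0
    latitude_richness_slope: float = -0.4  # species per degree
    plot_size_range: tuple[float, float] = (100.0, 1000.0)  # m²
    plot_size_richness_slope: float = 0.02  # species per m²
    richness_intercept: float = 40.0
    richness_noise_sd: float = 6.0
    dbic_scale: float = 6.0  # ΔBIC units per standardized unit

    def __post_init__(self):
        if self.n_regions < 8:
            raise ValueError("n_regions must be >= 8")
        if not (self.latitude_npp_slope < 0):
            raise ValueError("latitude_npp_slope must be negative")
        if not (-1.0 < self.npp_effect < 1.0 and -1.0 < self.richness_effect < 1.0):
            raise ValueError("standardized effects must lie in (-1, 1)")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in simulated column")
    return (x - x.mean()) / sd


def simulate_meta(scenario: MetaScenario) -> pd.DataFrame:
    """Draw region-level records (one row per region) for the meta-SEM."""
    sc = scenario
    streams = np.random.SeedSequence(sc.seed).spawn(5)
    rng_lat, rng_ps, rng_npp, rng_rich, rng_dbic = (np.random.default_rng(s) for s in streams)
    n = sc.n_regions

    lat = rng_lat.uniform(*sc.latitude_range, size=n)
    plot_size = rng_ps.uniform(*sc.plot_size_range, size=n)
    npp = sc.npp_intercept + sc.latitude_npp_slope * lat + rng_npp.normal(0, sc.npp_noise_sd, n)
    npp = np.clip(npp, 0.0, 3000.0)
    rich = (
        sc.richness_intercept
        + sc.latitude_richness_slope * lat
        + sc.plot_size_richness_slope * plot_size
        + rng_rich.normal(0, sc.richness_noise_sd, n)
    )
    rich = np.clip(rich, 1.0, None)

    z_npp, z_rich = _zscore(npp), _zscore(rich)
    structural = sc.npp_effect * z_npp + sc.richness_effect * z_rich
    resid_var = 1.0 - float(np.var(structural, ddof=1))
    noise_sd = math.sqrt(max(resid_var, 0.05))  # keep some noise even for large effects
    z_dbic = structural + rng_dbic.normal(0.0, noise_sd, size=n)
    dbic = sc.dbic_scale * z_dbic

    return pd.DataFrame(
        {
            "region_code": [f"R{i:02d}" for i in range(n)],
            "delta_bic": dbic,
            "npp": npp,
            "abs_latitude": lat,
            "mean_richness": rich,
            "plot_size": plot_size,
        }
    )


def scenario_with_seed(sc, seed: int):
    """Convenience: copy a scenario with a new seed (for replicate loops)."""
    return replace(sc, seed=seed)
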