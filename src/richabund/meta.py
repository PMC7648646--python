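"""Cross-region SEM: does climatological productivity set the causal direction?

Each forest region contributes one observation: its ΔBIC (negative when
richness→abundance is supported, positive when abundance→richness is),
its climatological NPP, its absolute latitude, its mean plot richness and
its plot size.  The structural hypothesis is that productivity controls
the causal direction while latitude acts only through climate and the
sampling protocol acts only through richness::

    abs_latitude → npp
    abs_latitude → mean_richness
    plot_size    → mean_richness
    npp          → delta_bic
    mean_richness→ delta_bic

All variables are z-scored before fitting so path coefficients are
standardized.  The d-separation basis set of this graph has four claims
(Fisher's C on 8 df); the claim that latitude is independent of ΔBIC given
NPP and richness is the test that no direct latitude→ΔBIC path is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psem import DagSpec, EquationSpec, PsemFit, fit_psem

__all__ = ["META_NODES", "MetaSemResult", "build_meta_model", "fit_meta"]

LAT = "abs_latitude"
PS = "plot_size"
NPP = "npp"
RICH = "mean_richness"
DBIC = "delta_bic"

META_NODES = (LAT, PS, NPP, RICH, DBIC)

META_EDGES = (
    (LAT, NPP),
    (LAT, RICH),
    (PS, RICH),
    (NPP, DBIC),
    (RICH, DBIC),
)


@dataclass
class MetaSemResult:
    """Standardized cross-region SEM estimates."""

    npp_coefficient: float
    richness_coefficient: float
    npp_p_value: float
    richness_p_value: float
    r_squared: float  # of the ΔBIC equation
    fisher_c: float
    df: int
    c_p_value: float
    latitude_claim_p: float  # missing-path test: ΔBIC ⊥ latitude | NPP, richness
    n_regions: int
    fit: PsemFit | None = None

    def to_dict(self) -> dict:
        return {
            "npp_coefficient": self.npp_coefficient,
            "richness_coefficient": self.richness_coefficient,
            "npp_p_value": self.npp_p_value,
            "richness_p_value": self.richness_p_value,
            "r_squared": self.r_squared,
            "fisher_c": self.fisher_c,
            "df": self.df,
            "c_p_value": self.c_p_value,
            "latitude_claim_p": self.latitude_claim_p,
            "n_regions": self.n_regions,
        }


def build_meta_model(predictor: str = NPP) -> tuple[DagSpec, tuple[EquationSpec, ...]]:
    """The cross-region DAG and its component regressions.

    ``predictor`` renames the productivity node (e.g. ``ndvi``) for
    sensitivity runs; the topology is unchanged.
    """
    rename = {NPP: predictor}
    nodes = tuple(rename.get(n, n) for n in META_NODES)
    edges = tuple((rename.get(u, u), rename.get(v, v)) for u, v in META_EDGES)
    dag = DagSpec(nodes=nodes, edges=edges)
    equations = tuple(
        EquationSpec(response=node, predictors=dag.parents(node))
        for node in (rename.get(NPP, NPP), RICH, DBIC)
    )
    return dag, equations


def standardize(records: pd.DataFrame, columns) -> pd.DataFrame:
    """Z-score the given columns; errors on zero-variance input."""
    out = records.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (x - x.mean()) / sd
    return out


def fit_meta(records: pd.DataFrame, predictor: str = NPP, min_regions: int = 8) -> MetaSemResult:
    """Fit the cross-region SEM on one row per region.

    Requires complete cases on abs_latitude, plot_size, the productivity
    predictor, mean_richness and delta_bic, and at least ``min_regions``
    regions (fewer rows than parameters cannot identify the paths).
    """
    dag, equations = build_meta_model(predictor)
    missing = [c for c in dag.nodes if c not in records.columns]
    if missing:
        raise ValueError(f"meta table missing columns: {missing}")
    frame = records[list(dag.nodes)].dropna()
    if len(frame) < min_regions:
        raise ValueError(f"need at least {min_regions} regions, got {len(frame)}")
    frame = standardize(frame, dag.nodes)

    fit = fit_psem(dag, list(equations), frame)

    dbic_fit = next(c for c in fit.components if c.response == DBIC)
    n = dbic_fit.n
    n_coef = len(dbic_fit.predictors) + 1
    # standardized response: total sum of squares is (n - 1)
    ss_resid = dbic_fit.residual_variance * (n - n_coef)
    r2 = 1.0 - ss_resid / (n - 1)

    lat_claim = next(cl for cl in fit.claims if {cl.x, cl.y} == {LAT, DBIC})
    return MetaSemResult(
        npp_coefficient=dbic_fit.coefficients[predictor],
        richness_coefficient=dbic_fit.coefficients[RICH],
        npp_p_value=dbic_fit.p_values[predictor],
        richness_p_value=dbic_fit.p_values[RICH],
        r_squared=float(r2),
        fisher_c=fit.fisher_c,
        df=fit.df,
        c_p_value=fit.c_p_value,
        latitude_claim_p=float(lat_claim.p_value),
        n_regions=fit.n,
        fit=fit,
    )
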