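"""GWAS phenotypes derived from detected meioses.

Two per-animal phenotypes:

* adjusted recombination rate — the residual of genome-wide crossover
  count after ordinary least squares on SNP density and the
  informative-marker counts of donor and offspring, averaged over the
  donor's meioses;
* hotspot usage — the proportion of crossover mass falling in hotspot
  intervals per meiosis, averaged over meioses with at least one
  crossover.

Fit the adjustment within breed x sex (callers group records first)
so breed/sex differences in mean crossover count do not leak into the
residuals.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .hotspots import HotspotSet


def adjusted_recombination_rate(meioses, return_model: bool = False):
    """Per-donor mean residual crossover count after covariate adjustment.

    Covariates: SNP density (typed-marker count of the donor-offspring
    pair), donor informative markers, offspring informative markers,
    plus an intercept.  Collinear/constant covariates are dropped with
    a warning.  Returns columns ``animal``, ``phenotype``, ``n_meioses``.
    """
    meioses = list(meioses)
    if len(meioses) < 2:
        raise ValueError("need at least two meioses to fit the adjustment")
    y = np.array([r.n_crossovers for r in meioses], dtype=float)
    cov = pd.DataFrame({
        "density": [r.density for r in meioses],
        "donor_informative": [r.donor_informative for r in meioses],
        "offspring_informative": [r.offspring_informative for r in meioses],
    }, dtype=float)

    keep = [c for c in cov.columns if cov[c].nunique() > 1]
    dropped = set(cov.columns) - set(keep)
    X = sm.add_constant(cov[keep], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    while rank < X.shape[1] and len(keep) > 0:
        dropped.add(keep[-1])
        keep = keep[:-1]
        X = sm.add_constant(cov[keep], has_constant="add")
        rank = np.linalg.matrix_rank(X.to_numpy())
    if dropped:
        warnings.warn(f"dropped collinear/constant covariates: {sorted(dropped)}")

    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    df = pd.DataFrame({
        "animal": [r.donor for r in meioses],
        "resid": resid,
    })
    out = df.groupby("animal", sort=True).agg(
        phenotype=("resid", "mean"), n_meioses=("resid", "size")
    ).reset_index()
    if return_model:
        return out, fit
    return out


def hotspot_usage(meioses, hotspots: HotspotSet) -> pd.DataFrame:
    """Per-donor mean share of crossover mass inside hotspot intervals.

    Meioses with zero crossovers carry no usage value (0/0) and are
    skipped; animals with only such meioses are absent from the result.
    """
    hot_arr = np.array(sorted(hotspots.rows), dtype=np.int64)
    rows = []
    for r in meioses:
        total = r.total_mass
        if total <= 0:
            continue
        in_hot = float(r.masses[np.isin(r.interval_rows, hot_arr)].sum()) \
            if hot_arr.size else 0.0
        rows.append((r.donor, in_hot / total))
    if not rows:
        return pd.DataFrame(columns=["animal", "phenotype", "n_meioses"])
    df = pd.DataFrame(rows, columns=["animal", "usage"])
    out = df.groupby("animal", sort=True).agg(
        phenotype=("usage", "mean"), n_meioses=("usage", "size")
    ).reset_index()
    return out
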