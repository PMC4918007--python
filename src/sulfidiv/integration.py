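"""System-level divergence scores and the headline correlations.

Combines per-individual divergence-vector scores into one value per
sulfide-spring system, merges the life-history and body-shape axes into
a single phenotypic-divergence variable by a correlation-matrix PCA, and
correlates that variable (one-tailed) with neutral genetic
differentiation and with H2S concentration.

Sign convention: divergence vectors are oriented sulfidic-positive, so
the literal "mean non-sulfidic minus sulfidic" difference is typically
negative; the summary reports both the signed difference and its
magnitude, and the PCA operates on magnitudes so that the
divergence-vs-H2S correlation has an unambiguous expected sign.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "DivergencePCA",
    "system_divergence_scores",
    "combine_divergence_pca",
    "correlate_onetailed",
    "one_tailed_p_from_r",
    "build_divergence_summary",
    "haversine_km",
]


@dataclass
class CorrelationResult:
    """Correlation coefficient with a one-tailed p-value."""

    r: float
    p: float
    n: int
    kind: str
    method: str

    def as_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n, "kind": self.kind,
                "method": self.method}


@dataclass
class DivergencePCA:
    """PC1 of two standardized divergence measures.

    For two standardized variables with correlation ``r`` the leading
    eigenvalue of the correlation matrix is ``1 + |r|`` and PC1 explains
    ``(1 + |r|) / 2`` of the variance.
    """

    scores: pd.Series
    eigenvalue: float
    variance_fraction: float
    correlation: float


# ---------------------------------------------------------------------------


def system_divergence_scores(
    scores: pd.Series,
    site_ids: pd.Series,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Per-system divergence: mean non-sulfidic minus sulfidic score.

    Per-site mean scores are computed first; the non-sulfidic site means
    of a system are then averaged and the sulfidic site mean subtracted.
    Systems missing scored individuals in either habitat are excluded
    with a warning.  Returns one row per system with the signed
    difference and its magnitude.
    """
    df = pd.DataFrame({"score": np.asarray(scores, dtype=float),
                       "site_id": np.asarray(site_ids)})
    site_means = df.groupby("site_id")["score"].mean()
    meta = sites.set_index("site_id")
    rows = []
    for system, grp in meta.groupby("system_id"):
        sulf = grp.index[grp["sulfidic"].astype(bool)]
        nonsulf = grp.index[~grp["sulfidic"].astype(bool)]
        sulf_scored = [s for s in sulf if s in site_means.index]
        nonsulf_scored = [s for s in nonsulf if s in site_means.index]
        if not sulf_scored or not nonsulf_scored:
            warnings.warn(
                f"system {system!r} lacks scored individuals in one habitat; "
                "excluded",
                stacklevel=2,
            )
            continue
        signed = float(
            site_means.loc[nonsulf_scored].mean() - site_means.loc[sulf_scored].mean()
        )
        rows.append(
            {
                "system_id": system,
                "divergence_signed": signed,
                "divergence_magnitude": abs(signed),
                "n_sites_sulfidic": len(sulf_scored),
                "n_sites_nonsulfidic": len(nonsulf_scored),
            }
        )
    return pd.DataFrame(rows).sort_values("system_id").reset_index(drop=True)


def combine_divergence_pca(lh: pd.Series, morph: pd.Series) -> DivergencePCA:
    """Correlation-matrix PCA of two per-system divergence measures.

    Each measure is z-standardized; PC1 of the 2x2 correlation matrix is
    returned with its eigenvalue and variance fraction.  Requires at
    least three systems with both measures and non-zero variance in
    each.
    """
    joined = pd.concat({"lh": lh, "morph": morph}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 systems with both divergence measures")
    sd = joined.std(ddof=1)
    if (sd == 0).any():
        raise ValueError("zero variance in a divergence measure")
    Z = (joined - joined.mean()) / sd
    r = float(Z["lh"].corr(Z["morph"]))
    sgn = 1.0 if r >= 0 else -1.0
    pc1 = (Z["lh"] + sgn * Z["morph"]) / np.sqrt(2.0)
    return DivergencePCA(
        scores=pc1,
        eigenvalue=1.0 + abs(r),
        variance_fraction=(1.0 + abs(r)) / 2.0,
        correlation=r,
    )


# ---------------------------------------------------------------------------
# One-tailed correlations


def one_tailed_p_from_r(r: float, n: int) -> float:
    """One-tailed p for a correlation via the t approximation.

    ``t = |r| sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of
    freedom, one tail in the direction of the observed sign.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return float(np.finfo(float).tiny)
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(max(stats.t.sf(t, n - 2), np.finfo(float).tiny))


def correlate_onetailed(
    x,
    y,
    kind: str = "spearman",
    method: str = "t_approx",
) -> CorrelationResult:
    """Pearson or Spearman correlation with a one-tailed p-value.

    Spearman uses average ranks for ties.  ``t_approx`` converts the
    coefficient to a t statistic on ``n - 2`` df; ``exact_perm``
    enumerates all ``n!`` permutations (n <= 10) and counts coefficients
    at least as extreme in the observed direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if kind == "spearman":
        xv = stats.rankdata(x)
        yv = stats.rankdata(y)
    elif kind == "pearson":
        xv, yv = x, y
    else:
        raise ValueError("kind must be 'pearson' or 'spearman'")
    r = float(np.corrcoef(xv, yv)[0, 1])
    if method == "t_approx":
        p = one_tailed_p_from_r(r, n)
    elif method == "exact_perm":
        if n > 10:
            raise ValueError("exact_perm limited to n <= 10")
        hits = 0
        total = 0
        sgn = 1.0 if r >= 0 else -1.0
        for perm in itertools.permutations(range(n)):
            rp = float(np.corrcoef(xv, yv[list(perm)])[0, 1])
            if sgn * rp >= sgn * r - 1e-12:
                hits += 1
            total += 1
        p = hits / total
    else:
        raise ValueError("method must be 't_approx' or 'exact_perm'")
    return CorrelationResult(r=r, p=p, n=n, kind=kind, method=method)


# ---------------------------------------------------------------------------
# Assembly


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in kilometres."""
    rlat1, rlon1, rlat2, rlon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = rlat2 - rlat1
    dlon = rlon2 - rlon1
    a = np.sin(dlat / 2) ** 2 + np.cos(rlat1) * np.cos(rlat2) * np.sin(dlon / 2) ** 2
    return float(2 * 6371.0 * np.arcsin(np.sqrt(a)))


def build_divergence_summary(
    lh_system: pd.DataFrame,
    morph_system: pd.DataFrame,
    sites: pd.DataFrame,
    fst: pd.DataFrame | None = None,
    pairing: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, CorrelationResult]]:
    """Per-system summary and the three headline one-tailed correlations.

    Takes the outputs of :func:`system_divergence_scores` for the
    life-history and body-shape axes, attaches each system's mean H2S
    concentration, the combined phenotypic PC1, and the theta between
    the sulfidic site and its geographically closest non-sulfidic site
    (``pairing`` overrides the distance rule; systems without genotype
    data are dropped from the F_ST correlation only).

    Returns ``(summary, correlations)`` with Spearman rank correlations
    for life-history vs. morphology (magnitudes), phenotypic PC1 vs.
    theta, and phenotypic PC1 vs. H2S.
    """
    meta = sites.set_index("site_id")
    lh = lh_system.set_index("system_id")
    mo = morph_system.set_index("system_id")
    systems = sorted(set(lh.index) | set(mo.index))
    rows = []
    for system in systems:
        grp = meta[meta["system_id"] == system]
        sulf_sites = grp.index[grp["sulfidic"].astype(bool)].tolist()
        nonsulf_sites = grp.index[~grp["sulfidic"].astype(bool)].tolist()
        h2s = float(grp.loc[sulf_sites, "h2s_um"].mean()) if sulf_sites else np.nan
        theta = np.nan
        partner = None
        if fst is not None and sulf_sites:
            s = sulf_sites[0]
            if pairing and system in pairing:
                partner = pairing[system]
            else:
                candidates = [
                    c
                    for c in nonsulf_sites
                    if c in getattr(fst, "columns", [])
                    and s in getattr(fst, "index", [])
                    and np.isfinite(fst.loc[s, c])
                ]
                if candidates:
                    if {"latitude", "longitude"}.issubset(grp.columns) and not (
                        grp[["latitude", "longitude"]].isna().any().any()
                    ):
                        partner = min(
                            candidates,
                            key=lambda c: haversine_km(
                                grp.loc[s, "latitude"],
                                grp.loc[s, "longitude"],
                                grp.loc[c, "latitude"],
                                grp.loc[c, "longitude"],
                            ),
                        )
                    else:
                        partner = candidates[0]
            if (
                partner is not None
                and s in getattr(fst, "index", [])
                and partner in getattr(fst, "columns", [])
            ):
                theta = float(fst.loc[s, partner])
        rows.append(
            {
                "system_id": system,
                "lh_divergence_signed": lh["divergence_signed"].get(system, np.nan),
                "lh_divergence": lh["divergence_magnitude"].get(system, np.nan),
                "morph_divergence_signed": mo["divergence_signed"].get(system, np.nan),
                "morph_divergence": mo["divergence_magnitude"].get(system, np.nan),
                "h2s_um": h2s,
                "fst_nearest": theta,
                "fst_partner": partner,
            }
        )
    summary = pd.DataFrame(rows).set_index("system_id")
    pca = combine_divergence_pca(summary["lh_divergence"], summary["morph_divergence"])
    summary["phen_pc1"] = pca.scores
    correlations: dict[str, CorrelationResult] = {}
    both = summary.dropna(subset=["lh_divergence", "morph_divergence"])
    correlations["lh_vs_morph"] = correlate_onetailed(
        both["lh_divergence"], both["morph_divergence"]
    )
    with_fst = summary.dropna(subset=["phen_pc1", "fst_nearest"])
    if len(with_fst) >= 3:
        correlations["phen_vs_fst"] = correlate_onetailed(
            with_fst["phen_pc1"], with_fst["fst_nearest"]
        )
    with_h2s = summary.dropna(subset=["phen_pc1", "h2s_um"])
    if len(with_h2s) >= 3:
        correlations["phen_vs_h2s"] = correlate_onetailed(
            with_h2s["phen_pc1"], with_h2s["h2s_um"]
        )
    summary.attrs["pc1_eigenvalue"] = pca.eigenvalue
    summary.attrs["pc1_variance_fraction"] = pca.variance_fraction
    return summary.reset_index(), correlations
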