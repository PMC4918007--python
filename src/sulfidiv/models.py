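"""Nested (M)AN(C)OVA machinery, Wilks statistics and divergence vectors.

Fits fixed-effects multivariate linear models with sum-to-zero contrasts
and Type-III hypothesis SSCP matrices, evaluates each term with Wilks'
lambda and Rao's F approximation, prunes non-significant interactions
hierarchically, tests the between-site factors at the site level
(site as the unit of replication), and extracts the canonical divergence
vector of a focal term — the linear combination of responses that
maximally separates habitat types while controlling for everything else
in the model.

Covariates are centred at their training means when the design matrix is
built, which makes main effects interpretable in the presence of
covariate-by-factor interactions and puts estimated marginal means at
covariate means by default.  The random site term of the source design
is represented by sum-coded site contrasts nested within the
clade-by-habitat cells; the dedicated :func:`site_level_test` provides
the between-site tests for which the individual-level residual would be
the wrong error stratum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "ModelSpec",
    "TermResult",
    "DivergenceVector",
    "MultivariateFit",
    "TransformRecord",
    "DEFAULT_TRAIT_TRANSFORMS",
    "transform_traits",
    "all_interactions",
    "fit_mglm",
    "wilks_stats",
    "prune_model",
    "site_level_test",
    "divergence_vector",
    "project_scores",
    "estimated_marginal_means",
    "ancova_slopes",
]


# ---------------------------------------------------------------------------
# Trait transformations

DEFAULT_TRAIT_TRANSFORMS: dict[str, str] = {
    "sl_mm": "log10",
    "lean_weight_g": "log10",
    "embryo_lean_weight_mg": "log10",
    "fecundity": "sqrt",
    "fat_content": "asin_sqrt",
    "gsi_or_ra": "asin_sqrt",
    "embryo_fat": "asin_sqrt",
}


@dataclass
class TransformRecord:
    """Per-variable transform names plus the z-scaling constants."""

    mapping: dict[str, str]
    means: dict[str, float]
    sds: dict[str, float]

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        """Undo z-scaling and the variance-stabilizing transforms."""
        out = table.copy()
        for col, name in self.mapping.items():
            if col not in out.columns:
                continue
            x = out[col] * self.sds[col] + self.means[col]
            if name == "log10":
                out[col] = 10.0**x
            elif name == "sqrt":
                out[col] = x**2
            elif name == "asin_sqrt":
                out[col] = np.sin(x) ** 2
            else:  # pragma: no cover
                raise ValueError(f"unknown transform {name!r}")
        out.attrs["transform_state"] = "raw"
        return out


def transform_traits(
    table: pd.DataFrame,
    mapping: dict[str, str] | None = None,
    zscore: bool = True,
) -> tuple[pd.DataFrame, TransformRecord]:
    """Variance-stabilize and z-standardize life-history variables.

    Lengths and weights are log10-transformed, counts square-root
    transformed, and proportions arcsine-square-root transformed; each
    transformed column is then centred and scaled to unit standard
    deviation.  Missing values pass through untouched (embryo traits are
    absent for males).  Raises on a log of a non-positive value or an
    arcsine-sqrt argument outside [0, 1].
    """
    if table.attrs.get("transform_state") == "transformed":
        raise ValueError("table is already transformed")
    mapping = dict(DEFAULT_TRAIT_TRANSFORMS if mapping is None else mapping)
    out = table.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    used: dict[str, str] = {}
    for col, name in mapping.items():
        if col not in out.columns:
            continue
        x = out[col].astype(float)
        valid = x.dropna()
        if name == "log10":
            if (valid <= 0).any():
                raise ValueError(f"log10 transform of non-positive value in {col!r}")
            t = np.log10(x)
        elif name == "sqrt":
            if (valid < 0).any():
                raise ValueError(f"sqrt transform of negative value in {col!r}")
            t = np.sqrt(x)
        elif name == "asin_sqrt":
            if ((valid < 0) | (valid > 1)).any():
                raise ValueError(
                    f"arcsine-sqrt transform outside [0, 1] in {col!r}"
                )
            t = np.arcsin(np.sqrt(x))
        else:
            raise ValueError(f"unknown transform {name!r} for {col!r}")
        if zscore:
            mu = float(t.mean())
            sd = float(t.std(ddof=1))
            if not np.isfinite(sd) or sd == 0:
                sd = 1.0
            out[col] = (t - mu) / sd
        else:
            mu, sd = 0.0, 1.0
            out[col] = t
        means[col], sds[col], used[col] = mu, sd, name
    out.attrs["transform_state"] = "transformed"
    return out, TransformRecord(mapping=used, means=means, sds=sds)


# ---------------------------------------------------------------------------
# Model specification and design matrices


@dataclass
class ModelSpec:
    """Specification of one multivariate linear model.

    ``nested_random`` names a grouping column (the site) together with
    the fixed factors whose cells it is nested in, e.g.
    ``("site_id", ("clade", "sulfidic"))``.  ``interactions`` is an
    explicit list of component tuples; :func:`all_interactions` builds
    the full candidate set of two- and three-way interactions.
    """

    dependents: list[str]
    fixed_factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    nested_random: tuple[str, tuple[str, ...]] | None = None
    interactions: list[tuple[str, ...]] = field(default_factory=list)

    def term_names(self) -> list[str]:
        names = list(self.covariates) + list(self.fixed_factors)
        if self.nested_random is not None:
            site, nest = self.nested_random
            names.append(f"{site}({'×'.join(nest)})")
        names += [":".join(t) for t in self.interactions]
        return names


def all_interactions(terms: list[str], max_order: int = 3) -> list[tuple[str, ...]]:
    """All 2-way up to ``max_order``-way interactions among ``terms``."""
    out: list[tuple[str, ...]] = []
    for order in range(2, max_order + 1):
        out.extend(itertools.combinations(terms, order))
    return out


@dataclass
class _DesignInfo:
    factor_levels: dict[str, list]
    cov_means: dict[str, float]
    cov_ranges: dict[str, tuple[float, float]]
    nested_cells: dict[tuple, list] | None
    column_names: list[str]
    term_cols: dict[str, list[int]]


def _factor_block(
    values: pd.Series, levels: list, name: str
) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) coding: L-1 columns, last level = -1."""
    codes = pd.Categorical(values, categories=levels).codes
    if (codes < 0).any():
        bad = sorted(set(values[codes < 0]))
        raise ValueError(f"unknown level(s) {bad} for factor {name!r}")
    n, L = len(values), len(levels)
    M = np.zeros((n, max(L - 1, 0)))
    for j in range(L - 1):
        M[codes == j, j] = 1.0
    M[codes == L - 1, :] = -1.0
    names = [f"{name}[{levels[j]}]" for j in range(L - 1)]
    return M, names


def _nested_block(
    data: pd.DataFrame,
    site_col: str,
    nest: tuple[str, ...],
    cells: dict[tuple, list],
) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    cols: list[np.ndarray] = []
    names: list[str] = []
    nest_vals = list(zip(*(data[f] for f in nest))) if n else []
    site_vals = data[site_col] if site_col in data.columns else pd.Series([np.nan] * n)
    for cell in sorted(cells, key=repr):
        sites = cells[cell]
        if len(sites) < 2:
            continue
        in_cell = np.array([v == cell for v in nest_vals], dtype=bool)
        last = sites[-1]
        for s in sites[:-1]:
            col = np.zeros(n)
            col[in_cell & (site_vals == s).to_numpy()] = 1.0
            col[in_cell & (site_vals == last).to_numpy()] = -1.0
            cols.append(col)
            names.append(f"{site_col}[{s}|{'×'.join(map(str, cell))}]")
    M = np.column_stack(cols) if cols else np.zeros((n, 0))
    return M, names


def _build_info(data: pd.DataFrame, spec: ModelSpec) -> _DesignInfo:
    levels = {
        f: sorted(pd.unique(data[f]).tolist(), key=repr)
        for f in spec.fixed_factors
    }
    cov_means = {c: float(data[c].mean()) for c in spec.covariates}
    cov_ranges = {
        c: (float(data[c].min()), float(data[c].max())) for c in spec.covariates
    }
    nested_cells = None
    if spec.nested_random is not None:
        site_col, nest = spec.nested_random
        nested_cells = {}
        for cell, grp in data.groupby(list(nest), sort=True):
            if not isinstance(cell, tuple):
                cell = (cell,)
            nested_cells[cell] = sorted(pd.unique(grp[site_col]).tolist())
    info = _DesignInfo(
        factor_levels=levels,
        cov_means=cov_means,
        cov_ranges=cov_ranges,
        nested_cells=nested_cells,
        column_names=[],
        term_cols={},
    )
    # establish column layout from the training data
    X, names, term_cols = _encode(data, spec, info, layout=True)
    info.column_names = names
    info.term_cols = term_cols
    return info


def _encode(
    data: pd.DataFrame,
    spec: ModelSpec,
    info: _DesignInfo,
    layout: bool = False,
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Build the design matrix for ``data`` under a fixed layout."""
    n = len(data)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["Intercept"]
    term_cols: dict[str, list[int]] = {"Intercept": [0]}
    pos = 1

    def add(term: str, M: np.ndarray, cnames: list[str]) -> None:
        nonlocal pos
        blocks.append(M)
        names.extend(cnames)
        term_cols[term] = list(range(pos, pos + M.shape[1]))
        pos += M.shape[1]

    comp_block: dict[str, tuple[np.ndarray, list[str]]] = {}
    for c in spec.covariates:
        col = (data[c].to_numpy(dtype=float) - info.cov_means[c])[:, None]
        comp_block[c] = (col, [c])
        add(c, col, [c])
    for f in spec.fixed_factors:
        M, cn = _factor_block(data[f], info.factor_levels[f], f)
        comp_block[f] = (M, cn)
        add(f, M, cn)
    if spec.nested_random is not None and info.nested_cells is not None:
        site_col, nest = spec.nested_random
        M, cn = _nested_block(data, site_col, nest, info.nested_cells)
        add(f"{site_col}({'×'.join(nest)})", M, cn)
    for terms in spec.interactions:
        M, cn = comp_block[terms[0]]
        cn = list(cn)
        for t in terms[1:]:
            M2, cn2 = comp_block[t]
            M = np.einsum("ni,nj->nij", M, M2).reshape(n, -1)
            cn = [f"{a}:{b}" for a in cn for b in cn2]
        add(":".join(terms), M, cn)
    X = np.concatenate(blocks, axis=1)
    return X, names, term_cols


# ---------------------------------------------------------------------------
# Fitting and Wilks statistics


@dataclass
class TermResult:
    """Wilks-based test of one model term."""

    term: str
    H: np.ndarray
    dfh: int
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    relative_variance: float | None = None
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "dfh": self.dfh,
            "wilks_lambda": self.wilks_lambda,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "partial_eta_sq": self.partial_eta_sq,
            "relative_variance": self.relative_variance,
            "note": self.note,
        }


def wilks_stats(
    H: np.ndarray, E: np.ndarray, dfh: int, dfe: int, term: str = ""
) -> TermResult:
    """Wilks' lambda with Rao's F approximation and partial eta squared.

    ``lambda = det(E) / det(H + E)``; the F approximation is exact for
    p <= 2 responses or dfh <= 2.  ``partial_eta_sq = 1 - lambda**(1/s)``
    with ``s = min(p, dfh)``.
    """
    H = np.asarray(H, dtype=float)
    E = np.asarray(E, dtype=float)
    p = E.shape[0]
    try:
        linalg.cholesky(E)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "residual SSCP is singular; reduce the number of responses "
            "or collect more observations"
        ) from exc
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_he, logdet_he = np.linalg.slogdet(H + E)
    lam = float(np.exp(logdet_e - logdet_he))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    q = dfh
    denom = p**2 + q**2 - 5
    t = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    w = dfe + q - (p + q + 1) / 2.0
    df1 = float(p * q)
    df2 = float(w * t - (p * q - 2) / 2.0)
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1 if df1 > 0 else np.nan
    pval = float(stats.f.sf(F, df1, df2)) if df2 > 0 else np.nan
    s = min(p, q)
    eta = float(1.0 - lam ** (1.0 / s))
    return TermResult(
        term=term,
        H=H,
        dfh=dfh,
        wilks_lambda=lam,
        F=float(F),
        df1=df1,
        df2=df2,
        p=pval,
        partial_eta_sq=eta,
    )


@dataclass
class MultivariateFit:
    """A fitted multivariate linear model with Type-III term SSCPs."""

    spec: ModelSpec
    info: _DesignInfo
    data: pd.DataFrame
    X: np.ndarray
    Y: np.ndarray
    B: np.ndarray
    E: np.ndarray
    dfe: int
    xtx_inv: np.ndarray
    _term_cache: dict[str, TermResult] = field(default_factory=dict)

    @property
    def dependents(self) -> list[str]:
        return list(self.spec.dependents)

    def hypothesis_sscp(self, term: str) -> tuple[np.ndarray, int]:
        """Type-III H of ``term``: full model vs. model without its columns."""
        cols = self.info.term_cols.get(term)
        if cols is None:
            raise KeyError(f"term {term!r} not in model; have {list(self.info.term_cols)}")
        keep = [j for j in range(self.X.shape[1]) if j not in set(cols)]
        Xr = self.X[:, keep]
        Br, *_ = np.linalg.lstsq(Xr, self.Y, rcond=None)
        Rr = self.Y - Xr @ Br
        Er = Rr.T @ Rr
        H = Er - self.E
        H = (H + H.T) / 2.0
        return H, len(cols)

    def term_test(self, term: str) -> TermResult:
        if term not in self._term_cache:
            H, dfh = self.hypothesis_sscp(term)
            self._term_cache[term] = wilks_stats(H, self.E, dfh, self.dfe, term=term)
        return self._term_cache[term]

    def term_tests(self) -> list[TermResult]:
        """All non-intercept terms, with relative variance attached.

        Relative variance is the term's partial variance divided by the
        largest partial variance in the model, so the strongest term
        scores 1.
        """
        results = [self.term_test(t) for t in self.info.term_cols if t != "Intercept"]
        max_eta = max((r.partial_eta_sq for r in results), default=np.nan)
        for r in results:
            r.relative_variance = (
                r.partial_eta_sq / max_eta if max_eta and max_eta > 0 else np.nan
            )
        return results

    def summary_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.term_tests()]
        df = pd.DataFrame(rows)
        return df.drop(columns=["note"]) if "note" in df else df


def fit_mglm(data: pd.DataFrame, spec: ModelSpec) -> MultivariateFit:
    """Fit the multivariate linear model by least squares.

    Complete cases only; sum-to-zero contrasts throughout; each term's
    hypothesis SSCP is computed by the Type-III full-vs-reduced
    comparison.  Raises on a rank-deficient design, naming the aliased
    columns.
    """
    used = (
        list(spec.dependents)
        + list(spec.fixed_factors)
        + list(spec.covariates)
        + ([spec.nested_random[0], *spec.nested_random[1]] if spec.nested_random else [])
    )
    used = list(dict.fromkeys(used))
    data = data.dropna(subset=[c for c in used if c in data.columns]).reset_index(
        drop=True
    )
    if data.empty:
        raise ValueError("no complete cases")
    info = _build_info(data, spec)
    X, names, term_cols = _encode(data, spec, info)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    Y = data[spec.dependents].to_numpy(dtype=float)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ B
    E = R.T @ R
    E = (E + E.T) / 2.0
    dfe = len(data) - X.shape[1]
    if dfe <= 0:
        raise ValueError("no residual degrees of freedom")
    return MultivariateFit(
        spec=spec,
        info=info,
        data=data,
        X=X,
        Y=Y,
        B=B,
        E=E,
        dfe=dfe,
        xtx_inv=np.linalg.pinv(X.T @ X),
    )


# ---------------------------------------------------------------------------
# Stepwise pruning of interactions


def prune_model(
    data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.1
) -> tuple[ModelSpec, MultivariateFit]:
    """Backward-prune interaction terms hierarchically.

    Repeatedly drops, among the highest-order interactions currently in
    the model, the one with the largest p-value above ``alpha`` — unless
    a retained higher-order interaction that contains it has p below
    ``alpha``.  Main effects, covariates and the nested site term are
    never dropped.  The model is refitted after every removal.
    """
    spec = replace(spec, interactions=list(spec.interactions))
    while True:
        fit = fit_mglm(data, spec)
        pvals = {r.term: r.p for r in (fit.term_test(":".join(t)) for t in spec.interactions)}
        candidates: list[tuple[int, float, tuple[str, ...]]] = []
        for terms in spec.interactions:
            name = ":".join(terms)
            p = pvals[name]
            if not (p > alpha):
                continue
            protected = any(
                set(terms) < set(other) and pvals[":".join(other)] < alpha
                for other in spec.interactions
            )
            if not protected:
                candidates.append((len(terms), p, terms))
        if not candidates:
            return spec, fit
        max_order = max(c[0] for c in candidates)
        _, _, drop = max(
            (c for c in candidates if c[0] == max_order), key=lambda c: c[1]
        )
        spec.interactions.remove(drop)


# ---------------------------------------------------------------------------
# Site-level tests of between-site fixed effects


def site_level_test(
    fit: MultivariateFit, term: str
) -> TermResult:
    """Test a between-site fixed effect with site as the replicate.

    Site mean response vectors (adjusted for the model's covariates via
    the pooled within-site regression) are analysed in a nested design:
    the hypothesis SSCP comes from the full factorial of the nesting
    factors, and the error SSCP is the variation among sites within
    clade-by-habitat cells, on ``n_sites - n_cells`` degrees of freedom.
    A documented approximation of a REML mixed-model F-test with
    adjusted degrees of freedom.
    """
    if fit.spec.nested_random is None:
        raise ValueError("site_level_test requires a nested_random term in the spec")
    site_col, nest = fit.spec.nested_random
    valid = list(nest) + [":".join(c) for c in itertools.combinations(nest, 2)]
    valid += [":".join(nest)] if len(nest) > 2 else []
    if term not in set(valid) | set(nest) and term != ":".join(nest):
        raise ValueError(f"term {term!r} is not a between-site effect of {nest}")
    data = fit.data
    # covariate-adjusted responses: remove covariate effects estimated
    # with site fixed effects absorbing between-site differences
    Y = data[fit.spec.dependents].to_numpy(dtype=float)
    if fit.spec.covariates:
        sites_dummies = pd.get_dummies(data[site_col]).to_numpy(dtype=float)
        C = np.column_stack(
            [data[c].to_numpy(dtype=float) - fit.info.cov_means[c] for c in fit.spec.covariates]
        )
        Xw = np.concatenate([sites_dummies, C], axis=1)
        Bw, *_ = np.linalg.lstsq(Xw, Y, rcond=None)
        Y = Y - C @ Bw[sites_dummies.shape[1]:]
    adj = pd.DataFrame(Y, columns=fit.spec.dependents)
    adj[site_col] = data[site_col].to_numpy()
    for f in nest:
        adj[f] = data[f].to_numpy()
    site_means = adj.groupby([site_col, *nest], sort=True, as_index=False).mean()
    n_sites = len(site_means)
    cells = site_means.groupby(list(nest), sort=True).size()
    n_cells = len(cells)
    if (cells < 2).any():
        singles = cells[cells < 2].index.tolist()
        warnings.warn(
            f"cell(s) {singles} contain a single site; the site-level test "
            f"for {term!r} has reduced (or no) replication there",
            stacklevel=2,
        )
    dfe = n_sites - n_cells
    if dfe < 1:
        raise ValueError("no site-level replication: every cell has a single site")
    site_spec = ModelSpec(
        dependents=list(fit.spec.dependents),
        fixed_factors=list(nest),
        interactions=all_interactions(list(nest), max_order=len(nest))
        if len(nest) > 1
        else [],
    )
    sfit = fit_mglm(site_means, site_spec)
    H, dfh = sfit.hypothesis_sscp(term)
    res = wilks_stats(H, sfit.E, dfh, sfit.dfe, term=term)
    res.note = "site-level nested test (site as unit of replication; approximation)"
    return res


# ---------------------------------------------------------------------------
# Divergence vectors


@dataclass
class DivergenceVector:
    """Canonical axis of a focal model term.

    ``coefficients`` (unit Euclidean norm, one weight per response)
    define the linear combination of responses with the greatest
    between-group separation relative to residual variation, controlling
    for all other model terms.  ``scores`` are per-individual projections
    of the responses adjusted for every non-focal term; ``center`` is the
    grand mean of the raw responses, used when projecting new
    individuals.
    """

    term: str
    dependents: list[str]
    coefficients: np.ndarray
    scores: np.ndarray
    orientation: str
    center: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.dependents, name=self.term)


def divergence_vector(
    fit: MultivariateFit, term: str = "sulfidic", positive_level=True
) -> DivergenceVector:
    """First canonical axis of ``E^-1 H`` for a focal model term.

    The leading generalized eigenvector maximizes the ratio of the
    term's hypothesis variation to residual variation along the axis.
    The vector is unit-normalized and oriented so the pooled mean score
    of ``positive_level`` (the sulfidic group by default) is at least
    that of the other groups.

    Scores are computed on responses adjusted for the model's nuisance
    terms: covariates and fixed effects not involving the focal factor.
    The focal term itself, interactions containing it, and the nested
    site term are left in the scores — site-level variation around the
    habitat means is part of the divergence signal the axis displays
    and is what the system-level summaries downstream consume.
    """
    H, dfh = fit.hypothesis_sscp(term)
    if dfh < 1:
        raise ValueError(f"term {term!r} has no hypothesis degrees of freedom")
    try:
        vals, vecs = linalg.eigh(H, fit.E)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "singular residual SSCP in canonical analysis"
        ) from exc
    a = vecs[:, -1]
    a = a / np.linalg.norm(a)
    nested_name = None
    if fit.spec.nested_random is not None:
        site_col, nest = fit.spec.nested_random
        nested_name = f"{site_col}({'×'.join(nest)})"
    nuisance_cols: list[int] = list(fit.info.term_cols["Intercept"])
    for name, cols in fit.info.term_cols.items():
        if name in ("Intercept", term, nested_name):
            continue
        if term in name.split(":"):
            continue
        nuisance_cols.extend(cols)
    Xo = fit.X[:, sorted(nuisance_cols)]
    Bo, *_ = np.linalg.lstsq(Xo, fit.Y, rcond=None)
    adjusted = fit.Y - Xo @ Bo
    scores = adjusted @ a
    if term in fit.data.columns:
        is_pos = (fit.data[term] == positive_level).to_numpy()
        if is_pos.any() and (~is_pos).any():
            if scores[is_pos].mean() < scores[~is_pos].mean():
                a = -a
                scores = -scores
    return DivergenceVector(
        term=term,
        dependents=list(fit.spec.dependents),
        coefficients=a,
        scores=scores,
        orientation=str(positive_level),
        center=fit.Y.mean(axis=0),
    )


def project_scores(
    vec: DivergenceVector,
    new_responses: pd.DataFrame | np.ndarray,
    pre_adjusted: bool = False,
) -> np.ndarray:
    """Project individuals onto a stored divergence vector.

    New individuals must carry the same (identically transformed)
    response variables; they are centred at the training grand mean and
    projected with the stored eigenvector coefficients.  Pass
    ``pre_adjusted=True`` when supplying responses already adjusted for
    the training model's non-focal terms (e.g. the training residuals
    themselves), in which case no centring is applied.
    """
    if isinstance(new_responses, pd.DataFrame):
        missing = [c for c in vec.dependents if c not in new_responses.columns]
        if missing:
            raise ValueError(f"missing response variable(s): {missing}")
        M = new_responses[vec.dependents].to_numpy(dtype=float)
    else:
        M = np.asarray(new_responses, dtype=float)
        if M.ndim == 1:
            M = M[None, :]
        if M.shape[1] != len(vec.dependents):
            raise ValueError(
                f"expected {len(vec.dependents)} responses, got {M.shape[1]}"
            )
    if not pre_adjusted:
        M = M - vec.center
    return M @ vec.coefficients


# ---------------------------------------------------------------------------
# Estimated marginal means


def estimated_marginal_means(
    fit: MultivariateFit,
    term: str,
    at: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Model-predicted means per level of a factor, at fixed covariates.

    Predictions are evaluated on the full grid of fixed-factor levels
    (covariates at their training means unless ``at`` overrides them,
    site contrasts averaged out) and averaged with equal weight over the
    non-focal factors.  Standard errors come from the coefficient
    covariance, with per-response residual variance ``E_rr / dfe``.
    Warns when a requested covariate value lies outside the observed
    range.
    """
    if term not in fit.spec.fixed_factors:
        raise ValueError(f"term {term!r} is not a fixed factor of the model")
    at = dict(at or {})
    for c, v in at.items():
        lo, hi = fit.info.cov_ranges[c]
        if v < lo or v > hi:
            warnings.warn(
                f"covariate {c}={v} outside the observed range [{lo}, {hi}]",
                stacklevel=2,
            )
    other = [f for f in fit.spec.fixed_factors if f != term]
    levels = fit.info.factor_levels[term]
    rows = []
    for lvl in levels:
        combos = itertools.product(*(fit.info.factor_levels[f] for f in other)) if other else [()]
        grid = []
        for combo in combos:
            rec = {term: lvl}
            rec.update(dict(zip(other, combo)))
            for c in fit.spec.covariates:
                rec[c] = at.get(c, fit.info.cov_means[c])
            if fit.spec.nested_random is not None:
                rec[fit.spec.nested_random[0]] = np.nan
            grid.append(rec)
        gdf = pd.DataFrame(grid)
        Xg, _, _ = _encode(gdf, fit.spec, fit.info)
        lvec = Xg.mean(axis=0)
        pred = lvec @ fit.B
        quad = float(lvec @ fit.xtx_inv @ lvec)
        for r, resp in enumerate(fit.spec.dependents):
            sigma2 = fit.E[r, r] / fit.dfe
            rows.append(
                {
                    "term": term,
                    "level": lvl,
                    "response": resp,
                    "emm": float(pred[r]),
                    "se": float(np.sqrt(sigma2 * quad)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Post-hoc ANCOVA on divergence scores


def ancova_slopes(
    lh_scores: np.ndarray | pd.Series,
    shape_scores: np.ndarray | pd.Series,
    site: np.ndarray | pd.Series,
    min_per_site: int = 3,
) -> pd.DataFrame:
    """ANCOVA of life-history scores on site, shape scores and their interaction.

    The site-by-covariate interaction tests slope heterogeneity across
    sites.  Sites with fewer than ``min_per_site`` individuals are
    excluded with a warning.  Returns an F table with rows for the site
    factor, the covariate, and the interaction.
    """
    df = pd.DataFrame(
        {
            "lh": np.asarray(lh_scores, dtype=float),
            "shape": np.asarray(shape_scores, dtype=float),
            "site": np.asarray(site),
        }
    ).dropna()
    counts = df["site"].value_counts()
    small = counts[counts < min_per_site].index.tolist()
    if small:
        warnings.warn(
            f"excluding site(s) with fewer than {min_per_site} individuals: {small}",
            stacklevel=2,
        )
        df = df[~df["site"].isin(small)]
    if df["site"].nunique() < 2:
        raise ValueError("ANCOVA requires at least two sites")
    spec = ModelSpec(
        dependents=["lh"],
        fixed_factors=["site"],
        covariates=["shape"],
        interactions=[("site", "shape")],
    )
    fit = fit_mglm(df, spec)
    rows = []
    for name in ["site", "shape", "site:shape"]:
        r = fit.term_test(name)
        rows.append(
            {"term": name, "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p}
        )
    return pd.DataFrame(rows)
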