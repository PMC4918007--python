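"""Microsatellite summaries, Weir–Cockerham F_ST and Mantel tests.

Neutral genetic differentiation between population pairs is the
pipeline's proxy for (the inverse of) gene flow.  Pairwise theta follows
the Weir & Cockerham (1984) analysis-of-variance estimator — per-allele
components ``a`` (among populations), ``b`` (among individuals within
populations) and ``c`` (within individuals), combined as a ratio of sums
over alleles and loci.  Negative per-locus components are retained
rather than truncated.  Matrix association is assessed with Mantel and
partial Mantel permutation tests; the partial test residualizes both
focal matrices on the covariate matrix (Smouse–Long–Sokal scheme) and
permutes the residualized dependent matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "PairwiseFst",
    "MantelResult",
    "read_genepop",
    "write_genepop",
    "genetic_variability",
    "pairwise_fst",
    "fst_matrix",
    "mantel",
    "partial_mantel",
    "binary_difference_matrix",
]


@dataclass
class GenotypeTable:
    """Diploid microsatellite calls per individual.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with positive
    integer allele labels (e.g. repeat sizes); 0 marks a missing allele,
    and both alleles of a locus are either present or missing.
    """

    individual_ids: list[str]
    site_ids: np.ndarray
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        n, L, two = self.calls.shape
        if two != 2:
            raise ValueError("calls must have shape (n, n_loci, 2)")
        if n != len(self.individual_ids) or n != len(self.site_ids):
            raise ValueError("individual/site id lengths do not match calls")
        if L != len(self.loci):
            raise ValueError("loci length does not match calls")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be non-negative integers")
        half_missing = (self.calls == 0).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("both alleles of a locus must be present or missing")

    @property
    def sites(self) -> list[str]:
        return sorted(pd.unique(self.site_ids).tolist())

    def subset_site(self, site: str) -> np.ndarray:
        return self.calls[self.site_ids == site]

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        rows["individual_id"] = self.individual_ids
        rows["site_id"] = self.site_ids
        for j, locus in enumerate(self.loci):
            rows[f"{locus}_a1"] = self.calls[:, j, 0]
            rows[f"{locus}_a2"] = self.calls[:, j, 1]
        return pd.DataFrame(rows)


@dataclass
class PairwiseFst:
    """Symmetric matrix of multilocus Weir–Cockerham theta estimates."""

    sites: list[str]
    matrix: pd.DataFrame
    components: pd.DataFrame  # per site pair and locus: a, b, c sums

    def theta(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


@dataclass
class MantelResult:
    """Mantel (or partial Mantel) matrix correlation and permutation p."""

    r: float
    p: float
    n_perm: int
    tails: str
    partial: bool = False
    covariate: str = ""


# ---------------------------------------------------------------------------
# GenePop input/output


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a GenePop file (2- or 3-digit allele coding).

    Population membership is taken from the sample labels (the text
    before the comma); ``000000``/``0000`` is missing.  Inconsistent
    locus counts raise a parse error with the offending line number.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("GenePop file too short")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [x.strip() for x in lines[i].split(",") if x.strip()]
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' separator found")
    ids: list[str] = []
    site_ids: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    digits: int | None = None
    pop_counter: dict[str, int] = {}
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            continue
        if "," not in line:
            raise ValueError(f"line {i}: expected 'label , genotypes', got {line!r}")
        label, geno = line.split(",", 1)
        label = label.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"line {i}: {len(fields)} genotypes for {len(loci)} loci"
            )
        row: list[tuple[int, int]] = []
        for f in fields:
            if digits is None:
                if len(f) == 4:
                    digits = 2
                elif len(f) == 6:
                    digits = 3
                else:
                    raise ValueError(
                        f"line {i}: genotype {f!r} is neither 4 nor 6 characters"
                    )
            if len(f) != 2 * digits or not f.isdigit():
                raise ValueError(f"line {i}: malformed genotype {f!r}")
            a1, a2 = int(f[:digits]), int(f[digits:])
            if (a1 == 0) != (a2 == 0):
                raise ValueError(f"line {i}: half-missing genotype {f!r}")
            row.append((a1, a2))
        k = pop_counter.get(label, 0)
        pop_counter[label] = k + 1
        ids.append(f"{label}_{k + 1}")
        site_ids.append(label)
        calls.append(row)
    return GenotypeTable(
        individual_ids=ids,
        site_ids=np.asarray(site_ids, dtype=object),
        loci=loci,
        calls=np.asarray(calls, dtype=int),
    )


def write_genepop(
    gt: GenotypeTable, path: str | Path, digits: int = 3, title: str = "sulfidiv export"
) -> None:
    """Write genotypes in GenePop format, one ``Pop`` block per site."""
    if (gt.calls >= 10**digits).any():
        raise ValueError(f"allele labels do not fit {digits}-digit coding")
    out = [title]
    out.extend(gt.loci)
    for site in gt.sites:
        out.append("Pop")
        mask = gt.site_ids == site
        for row in gt.calls[mask]:
            geno = " ".join(
                f"{a1:0{digits}d}{a2:0{digits}d}" for a1, a2 in row
            )
            out.append(f"{site} , {geno}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Variability summaries


def genetic_variability(gt: GenotypeTable) -> pd.DataFrame:
    """Per-site, per-locus sample size, allele count, Ho and unbiased He.

    ``Ho`` is the fraction of genotyped individuals that are
    heterozygous; ``He`` uses the small-sample correction
    ``(2n / (2n - 1)) * (1 - sum(p^2))``.  Loci with no genotyped
    individuals at a site are flagged with ``n = 0`` and missing values.
    """
    rows = []
    for site in gt.sites:
        block = gt.subset_site(site)
        for j, locus in enumerate(gt.loci):
            g = block[:, j, :]
            g = g[g[:, 0] > 0]
            n = g.shape[0]
            if n == 0:
                rows.append(
                    {
                        "site_id": site,
                        "locus": locus,
                        "n": 0,
                        "n_alleles": 0,
                        "ho": np.nan,
                        "he": np.nan,
                    }
                )
                continue
            alleles, counts = np.unique(g.ravel(), return_counts=True)
            p = counts / counts.sum()
            ho = float((g[:, 0] != g[:, 1]).mean())
            he = float((2 * n / (2 * n - 1)) * (1 - (p**2).sum())) if n > 0 else np.nan
            rows.append(
                {
                    "site_id": site,
                    "locus": locus,
                    "n": n,
                    "n_alleles": len(alleles),
                    "ho": ho,
                    "he": he,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def _wc_components_locus(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[float, float, float]:
    """Summed a, b, c variance components over alleles at one locus.

    ``g1``/``g2`` are ``(n_i, 2)`` arrays of positive allele labels
    (missing already removed) for the two populations.
    """
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        return 0.0, 0.0, 0.0
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    alleles = np.union1d(np.unique(g1), np.unique(g2))
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p1 = (g1 == al).sum() / (2 * n1)
        p2 = (g2 == al).sum() / (2 * n2)
        h1 = ((g1 == al).sum(axis=1) == 1).mean()
        h2 = ((g2 == al).sum(axis=1) == 1).mean()
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def pairwise_fst(
    gt: GenotypeTable, site_a: str, site_b: str
) -> tuple[float, pd.DataFrame]:
    """Multilocus Weir–Cockerham theta between two sites.

    Returns ``(theta, per_locus)`` where the per-locus table carries the
    a, b, c component sums and single-locus estimates (which may be
    negative).  Theta is the ratio of summed ``a`` to summed
    ``a + b + c``; when nothing varies anywhere the estimate is
    undefined and returned as missing with a warning.
    """
    ga = gt.subset_site(site_a)
    gb = gt.subset_site(site_b)
    rows = []
    for j, locus in enumerate(gt.loci):
        g1 = ga[:, j, :]
        g1 = g1[g1[:, 0] > 0]
        g2 = gb[:, j, :]
        g2 = g2[g2[:, 0] > 0]
        if g1.shape[0] < 2 or g2.shape[0] < 2:
            continue
        a, b, c = _wc_components_locus(g1, g2)
        denom = a + b + c
        rows.append(
            {
                "locus": locus,
                "a": a,
                "b": b,
                "c": c,
                "theta_locus": a / denom if denom != 0 else np.nan,
            }
        )
    per_locus = pd.DataFrame(rows)
    if per_locus.empty:
        warnings.warn(
            f"no shared genotyped locus between {site_a} and {site_b}", stacklevel=2
        )
        return np.nan, per_locus
    denom = float(per_locus["a"].sum() + per_locus["b"].sum() + per_locus["c"].sum())
    if denom == 0:
        warnings.warn(
            f"no variation at any locus between {site_a} and {site_b}; "
            "theta undefined",
            stacklevel=2,
        )
        return np.nan, per_locus
    return float(per_locus["a"].sum() / denom), per_locus


def fst_matrix(gt: GenotypeTable) -> PairwiseFst:
    """Symmetric pairwise theta matrix over all sites."""
    sites = gt.sites
    M = pd.DataFrame(0.0, index=sites, columns=sites)
    comp_rows = []
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            theta, per_locus = pairwise_fst(gt, a, b)
            M.loc[a, b] = M.loc[b, a] = theta
            per_locus = per_locus.assign(site_a=a, site_b=b)
            comp_rows.append(per_locus)
    components = (
        pd.concat(comp_rows, ignore_index=True) if comp_rows else pd.DataFrame()
    )
    return PairwiseFst(sites=sites, matrix=M, components=components)


# ---------------------------------------------------------------------------
# Mantel tests


def _as_matrix(A, labels=None) -> tuple[np.ndarray, list]:
    if isinstance(A, pd.DataFrame):
        if labels is not None:
            A = A.loc[labels, labels]
        return A.to_numpy(dtype=float), list(A.index)
    A = np.asarray(A, dtype=float)
    return A, labels if labels is not None else list(range(A.shape[0]))


def _check_square_symmetric(M: np.ndarray, name: str) -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-8, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")


def _upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def mantel(
    A,
    B,
    n_perm: int = 999,
    tails: str = "one",
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test between two distance/difference matrices.

    ``r`` is the Pearson correlation of upper-triangle entries; the null
    distribution comes from simultaneous row/column permutations of
    ``A``.  One-tailed p counts permuted correlations at least as large
    as the observed one, with the add-one convention
    ``p = (hits + 1) / (n_perm + 1)``.
    """
    Am, labels = _as_matrix(A)
    Bm, _ = _as_matrix(B, labels if isinstance(B, pd.DataFrame) else None)
    _check_square_symmetric(Am, "A")
    _check_square_symmetric(Bm, "B")
    if Am.shape != Bm.shape:
        raise ValueError("A and B must have the same shape")
    x = _upper(Am)
    y = _upper(Bm)
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = Am.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = float(np.corrcoef(_upper(Am[np.ix_(perm, perm)]), y)[0, 1])
        if tails == "one":
            if r_perm >= r_obs - 1e-12:
                hits += 1
        else:
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, tails=tails)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel(
    A,
    B,
    C,
    n_perm: int = 999,
    tails: str = "one",
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test of A vs. B controlling for C.

    Both A and B are residualized element-wise (over the upper triangle)
    on C; the Mantel permutation is then applied to the rebuilt residual
    matrices, permuting the residualized A.  A constant C falls back to
    the simple Mantel test with a warning.
    """
    Am, labels = _as_matrix(A)
    Bm, _ = _as_matrix(B, labels if isinstance(B, pd.DataFrame) else None)
    Cm, _ = _as_matrix(C, labels if isinstance(C, pd.DataFrame) else None)
    for M, nm in [(Am, "A"), (Bm, "B"), (Cm, "C")]:
        _check_square_symmetric(M, nm)
    if not (Am.shape == Bm.shape == Cm.shape):
        raise ValueError("A, B, C must be conformable")
    z = _upper(Cm)
    if np.nanstd(z) == 0:
        warnings.warn(
            "covariate matrix is constant; falling back to a simple Mantel test",
            stacklevel=2,
        )
        res = mantel(Am, Bm, n_perm=n_perm, tails=tails, seed=seed)
        return MantelResult(
            r=res.r, p=res.p, n_perm=n_perm, tails=tails, partial=False,
            covariate="constant (ignored)",
        )
    n = Am.shape[0]
    iu = np.triu_indices(n, k=1)

    def rebuild(resid_vec: np.ndarray) -> np.ndarray:
        M = np.zeros((n, n))
        M[iu] = resid_vec
        return M + M.T

    Ar = rebuild(_residualize(_upper(Am), z))
    Br = rebuild(_residualize(_upper(Bm), z))
    res = mantel(Ar, Br, n_perm=n_perm, tails=tails, seed=seed)
    return MantelResult(
        r=res.r, p=res.p, n_perm=n_perm, tails=tails, partial=True,
        covariate="residualized on C (Smouse-Long-Sokal)",
    )


def binary_difference_matrix(values: pd.Series) -> pd.DataFrame:
    """0/1 matrix: 0 for pairs sharing the attribute value, 1 otherwise.

    Used for the habitat-difference (sulfidic vs. non-sulfidic) and
    clade-difference matrices of the partial Mantel test.
    """
    labels = list(values.index)
    v = values.to_numpy()
    M = (v[:, None] != v[None, :]).astype(float)
    np.fill_diagonal(M, 0.0)
    return pd.DataFrame(M, index=labels, columns=labels)
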