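"""REML animal model for single-marker and haplotype association.

The model, for one trait in one lactation, is

    y = mu + HYS + b * M + G + u + e,
    u ~ N(0, A * sigma_a^2),   e ~ N(0, I * sigma_e^2)

where HYS is the fixed herd(farm)-year-season class, M the calving-age
covariate, G the genotype (or diplotype) factor, and u the random
additive-genetic animal effect with pedigree relationship matrix A.

Variance components are estimated by REML, profiled down to a
one-dimensional search over the ratio ``lambda = sigma_e^2 / sigma_a^2``.
Because every record maps to one animal, ``Z A Z'`` is just the
relationship matrix restricted to phenotyped animals; a single spectral
decomposition of that matrix makes each profile-likelihood evaluation
O(n p^2), so the bounded Brent search over log(lambda) is cheap.
Henderson's mixed-model equations (with the sparse ``A^{-1}``) are kept
for BLUP of the animal effects; the fixed-effect solutions and their
covariance are identical between the two routes.

Inference on G is a Wald chi-square on the genotype contrasts
(df = levels - 1).  LS-means are adjusted means at equal HYS weights and
the grand covariate mean; pairwise significance letters use the
insert-and-absorb grouping algorithm at 0.05 (lowercase) and 0.01
(uppercase).  Bonferroni correction multiplies the raw p by the family
size, uncapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve

from .pedigree import Pedigree

__all__ = ["AnimalModel", "AnimalModelResults", "bonferroni", "compact_letters"]


def bonferroni(pvalue: float, m: int) -> float:
    """Bonferroni-corrected p: raw p times family size, uncapped."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return pvalue * m


def compact_letters(levels: list, sig_pairs: set[frozenset], alphabet: str) -> dict:
    """Compact letter display by the insert-and-absorb algorithm.

    Levels sharing no common letter differ significantly; ``sig_pairs``
    holds the significantly different pairs.
    """
    columns: list[set] = [set(levels)]
    for pair in sorted(sig_pairs, key=lambda p: sorted(levels.index(x) for x in p)):
        a, b = sorted(pair, key=levels.index)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for new in (col - {a}, col - {b}):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
        columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: min(levels.index(x) for x in c))
    letters: dict = {lv: "" for lv in levels}
    for k, col in enumerate(columns):
        for lv in levels:
            if lv in col:
                letters[lv] += alphabet[k % len(alphabet)]
    return letters


class AnimalModel:
    """Mixed linear animal model for one trait.

    Parameters
    ----------
    data : pandas.DataFrame
        One record per row with at least ``animal`` and the trait column.
    trait : str
        Name of the response column.
    pedigree : Pedigree
        Source of the additive relationship matrix; every phenotyped
        animal must appear in it.
    factor : str, optional
        Genotype/diplotype factor column (the term under test).
    hys : str, optional
        Fixed-effect class column (herd-year-season); None to omit.
    covariate : str, optional
        Numeric covariate (calving age, months); None to omit.
    extra_factors : sequence of str
        Additional fixed-effect class columns (mostly for diagnostics).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait: str,
        pedigree: Pedigree,
        factor: str | None = None,
        hys: str | None = "hys",
        covariate: str | None = "calving_age",
        extra_factors: tuple[str, ...] = (),
    ) -> None:
        used = ["animal", trait]
        cat_terms = []
        if hys is not None:
            cat_terms.append(hys)
        cat_terms.extend(extra_factors)
        if factor is not None:
            cat_terms.append(factor)
        used += cat_terms
        if covariate is not None:
            used.append(covariate)
        df = data.loc[:, ~data.columns.duplicated()].reindex(columns=used)
        df = df.dropna()
        if df.empty:
            raise ValueError("no complete records")
        self.data = df.reset_index(drop=True)
        self.trait = trait
        self.factor = factor
        self.hys = hys
        self.covariate = covariate
        self.pedigree = pedigree

        pos = {a: i for i, a in enumerate(pedigree.ids)}
        try:
            self.record_animal_idx = np.array([pos[str(a)] for a in self.data["animal"]])
        except KeyError as exc:
            raise ValueError(f"animal {exc.args[0]!r} has phenotype but no pedigree record") from None

        self.endog = self.data[trait].to_numpy(dtype=float)
        cols = [np.ones(len(self.data))]
        names = ["Intercept"]
        self.term_slices: dict[str, np.ndarray] = {"Intercept": np.array([0])}
        self.term_levels: dict[str, list] = {}
        for term in cat_terms:
            levels = sorted(self.data[term].astype(str).unique())
            self.term_levels[term] = levels
            idx = []
            for lv in levels[1:]:
                idx.append(len(cols))
                cols.append((self.data[term].astype(str) == lv).to_numpy(float))
                names.append(f"{term}[{lv}]")
            self.term_slices[term] = np.array(idx, dtype=int)
        if covariate is not None:
            self.term_slices[covariate] = np.array([len(cols)])
            cols.append(self.data[covariate].to_numpy(dtype=float))
            names.append(covariate)
        self.exog = np.column_stack(cols)
        self.exog_names = names
        self._check_rank()
        self._eig = None

    # -- internals ---------------------------------------------------------

    def _check_rank(self) -> None:
        X = self.exog
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            from scipy.linalg import qr

            _, R, piv = qr(X, mode="economic", pivoting=True)
            thresh = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
            bad_cols = [piv[k] for k in range(X.shape[1]) if abs(R[k, k]) < thresh]
            terms = sorted(
                {t for t, idx in self.term_slices.items() if set(idx) & set(bad_cols)}
            )
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient; confounded terms: {terms or bad_cols}"
            )

    def _eigen(self):
        if self._eig is None:
            A = self.pedigree.additive_relationship().to_numpy()
            M = A[np.ix_(self.record_animal_idx, self.record_animal_idx)]
            w, U = np.linalg.eigh(M)
            w = np.clip(w, 0.0, None)
            self._eig = (w, U, U.T @ self.endog, U.T @ self.exog)
        return self._eig

    def _profile(self, lam: float):
        """Profiled REML pieces at a given lambda = sigma_e^2 / sigma_a^2."""
        w, _, yt, Xt = self._eigen()
        n, p = Xt.shape
        s = w / lam + 1.0
        inv = 1.0 / s
        XtHX = Xt.T @ (Xt * inv[:, None])
        XtHy = Xt.T @ (yt * inv)
        c, low = cho_factor(XtHX)
        beta = cho_solve((c, low), XtHy)
        r = yt - Xt @ beta
        ypy = float(r @ (r * inv))
        sigma_e2 = ypy / (n - p)
        logdet_XtHX = 2.0 * float(np.sum(np.log(np.diag(c))))
        neg2 = (n - p) * np.log(sigma_e2) + float(np.sum(np.log(s))) + logdet_XtHX
        return neg2, beta, sigma_e2, XtHX

    def fit(
        self,
        lam: float | None = None,
        bounds: tuple[float, float] = (1e-4, 1e4),
        tol: float = 1e-6,
    ) -> "AnimalModelResults":
        """Estimate variance components by REML and solve for fixed effects.

        Parameters
        ----------
        lam : float, optional
            Fix the variance ratio sigma_e^2/sigma_a^2 instead of
            estimating it (used by oracle tests and profiling).
        bounds : (float, float)
            Search interval for lambda.
        tol : float
            Relative convergence tolerance on lambda.
        """
        at_bound = False
        if lam is None:
            lo, hi = np.log(bounds[0]), np.log(bounds[1])
            res = optimize.minimize_scalar(
                lambda t: self._profile(np.exp(t))[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": tol * 0.1, "maxiter": 500},
            )
            lam = float(np.exp(res.x))
            if res.x < lo + 1e-3 or res.x > hi - 1e-3:
                at_bound = True
                warnings.warn(
                    "lambda at search bound: heritability estimate is ~0 or ~1",
                    stacklevel=2,
                )
        neg2, beta, sigma_e2, XtHX = self._profile(lam)
        n, p = self.exog.shape
        cov = sigma_e2 * np.linalg.inv(XtHX)
        llf = -0.5 * (neg2 + (n - p) * (1.0 + np.log(2.0 * np.pi)))
        return AnimalModelResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            lam=lam,
            sigma_e2=float(sigma_e2),
            sigma_a2=float(sigma_e2 / lam),
            llf=float(llf),
            nobs=n,
            df_resid=n - p,
            at_bound=at_bound,
        )

    # -- Henderson's mixed-model equations ---------------------------------

    def mme_matrices(self, lam: float):
        """Dense coefficient matrix and RHS of Henderson's MME at lambda."""
        n, p = self.exog.shape
        q = len(self.pedigree)
        X = self.exog
        Z = sparse.coo_matrix(
            (np.ones(n), (np.arange(n), self.record_animal_idx)), shape=(n, q)
        ).tocsr()
        Ainv = self.pedigree.a_inverse()
        Zd = Z.toarray()
        C = np.block(
            [
                [X.T @ X, X.T @ Zd],
                [Zd.T @ X, (Z.T @ Z + lam * Ainv).toarray()],
            ]
        )
        rhs = np.concatenate([X.T @ self.endog, Z.T @ self.endog])
        return C, rhs

    def solve_mme(self, lam: float):
        """Solve the MME; returns (fixed-effect solutions, BLUP of u)."""
        C, rhs = self.mme_matrices(lam)
        sol = np.linalg.solve(C, rhs)
        p = self.exog.shape[1]
        return sol[:p], pd.Series(sol[p:], index=self.pedigree.ids)


@dataclass
class AnimalModelResults:
    """Fitted animal model: variance components, fixed effects, tests."""

    model: AnimalModel
    params: pd.Series
    cov_params: pd.DataFrame
    lam: float
    sigma_e2: float
    sigma_a2: float
    llf: float
    nobs: int
    df_resid: int
    at_bound: bool = False
    _blup: pd.Series | None = field(default=None, repr=False)

    @property
    def heritability(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @property
    def random_effects(self) -> pd.Series:
        """BLUP of the additive-genetic animal effects (lazy MME solve)."""
        if self._blup is None:
            _, self._blup = self.model.solve_mme(self.lam)
        return self._blup

    # -- tests and means ---------------------------------------------------

    def wald_test(self, term: str | None = None) -> tuple[float, int, float]:
        """Wald chi-square for a fixed-effect class term; (chi2, df, p)."""
        term = term or self.model.factor
        idx = self.model.term_slices[term]
        if len(idx) == 0:  # single-level factor
            return 0.0, 0, 1.0
        b = self.params.to_numpy()[idx]
        V = self.cov_params.to_numpy()[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        return chi2, df, float(stats.chi2.sf(chi2, df))

    def _lsmean_rows(self, term: str) -> tuple[list, np.ndarray]:
        model = self.model
        levels = model.term_levels[term]
        p = len(model.exog_names)
        base = np.zeros(p)
        base[model.term_slices["Intercept"]] = 1.0
        for other, lv_list in model.term_levels.items():
            if other == term:
                continue
            k = len(lv_list)
            base[model.term_slices[other]] = 1.0 / k  # equal weight per class
        if model.covariate is not None:
            base[model.term_slices[model.covariate]] = float(
                model.data[model.covariate].mean()
            )
        rows = np.tile(base, (len(levels), 1))
        for j, lv in enumerate(levels[1:], start=1):
            rows[j, model.term_slices[term][j - 1]] = 1.0
        return levels, rows

    def ls_means(self, term: str | None = None) -> pd.DataFrame:
        """Adjusted means at equal HYS weights and the mean covariate."""
        term = term or self.model.factor
        levels, L = self._lsmean_rows(term)
        est = L @ self.params.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, self.cov_params.to_numpy(), L))
        counts = self.model.data[term].astype(str).value_counts()
        return pd.DataFrame(
            {
                "level": levels,
                "n": [int(counts.get(lv, 0)) for lv in levels],
                "lsmean": est,
                "se": se,
            }
        ).set_index("level")

    def pairwise_pvalues(self, term: str | None = None) -> pd.DataFrame:
        """Wald z-test p-values for all level pairs of a class term."""
        term = term or self.model.factor
        levels, L = self._lsmean_rows(term)
        V = self.cov_params.to_numpy()
        out = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels, columns=levels)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                d = L[i] - L[j]
                var = float(d @ V @ d)
                diff = float(d @ self.params.to_numpy())
                z = diff / np.sqrt(var) if var > 0 else 0.0
                pv = 2.0 * stats.norm.sf(abs(z))
                out.iloc[i, j] = out.iloc[j, i] = pv
        return out

    def letters(self, term: str | None = None) -> pd.DataFrame:
        """Significance letters: lowercase at p<0.05, uppercase at p<0.01."""
        term = term or self.model.factor
        pv = self.pairwise_pvalues(term)
        levels = list(pv.index)
        lower = compact_letters(
            levels,
            {frozenset((a, b)) for a in levels for b in levels if a < b and pv.loc[a, b] < 0.05},
            "abcdefghij",
        )
        upper = compact_letters(
            levels,
            {frozenset((a, b)) for a in levels for b in levels if a < b and pv.loc[a, b] < 0.01},
            "ABCDEFGHIJ",
        )
        return pd.DataFrame(
            {"letters_005": [lower[lv] for lv in levels], "letters_001": [upper[lv] for lv in levels]},
            index=levels,
        )

    def summary(self) -> str:
        lines = [
            "Animal model (REML)",
            "=" * 58,
            f"Trait: {self.model.trait:<20s}  Records: {self.nobs}",
            f"sigma_a^2: {self.sigma_a2:.6g}    sigma_e^2: {self.sigma_e2:.6g}",
            f"lambda (e/a): {self.lam:.6g}    h^2: {self.heritability:.4f}",
            f"REML log-likelihood: {self.llf:.4f}",
        ]
        if self.model.factor is not None:
            chi2, df, pv = self.wald_test()
            lines.append(
                f"{self.model.factor} Wald chi2 = {chi2:.4f} (df={df}), p = {pv:.4g}"
            )
            lines.append("-" * 58)
            lsm = self.ls_means().join(self.letters())
            lines.append(lsm.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
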