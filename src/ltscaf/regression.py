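"""Contig position estimation by weighted least trimmed squares.

The observation table from link clustering defines a linear model

    Y = X beta + eps,      eps_k ~ N(0, sigma_b^2 * pi / (2 n_k))

where each row k observes ``beta_j(k) - beta_i(k)`` (design row with -1 at
i(k), +1 at j(k)) and carries weight ``w_k = n_k / var_k``.  The anchor
contig's position is fixed to 0 for identifiability by eliminating its
column, so the weighted normal matrix ``X'WX`` is the weighted graph
Laplacian over the remaining contigs and the system is solvable exactly
when the observation graph is connected.

Because clustering may retain several contradictory modes per contig pair,
a fraction of rows are gross outliers.  The weighted least trimmed squares
(WLTS) estimator selects the inlier subset itself: starting from all rows,
it iteratively re-fits and keeps the rows with the smallest absolute
residuals — one fewer per iteration, re-selected from the full set each
time so a row can re-enter — until every selected residual is below
``MaxError`` (default 100 bp, raised by 50 per outer scaffolding round).
If the selected rows no longer connect the component, the component is
split and each part re-enters the pipeline at the orientation stage.

Usage follows the Model/Results convention::

    model = ContigPositionModel(obs, lengths)
    res = model.fit(max_error=100.0)
    res.params            # contig start coordinates (anchor at 0)
    res.gap_confidence()  # per-adjacent-pair gap estimates with CIs
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import cg, spsolve
from scipy.stats import norm, t as t_dist

log = logging.getLogger(__name__)

#: default residual bound (bp) for the trimming loop
DEFAULT_MAX_ERROR = 100.0
#: MaxError increment per outer scaffolding iteration
MAX_ERROR_STEP = 50.0
#: switch from a direct sparse solve to conjugate gradients above this size
CG_CONTIG_LIMIT = 50_000


def maxerror_schedule(base: float = DEFAULT_MAX_ERROR,
                      outer_iteration: int = 0) -> float:
    """Residual bound for outer round t: ``base + 50 * t``.

    Later rounds merge super-contigs with fewer, smaller clusters whose
    medians are noisier, so the bound relaxes linearly.
    """
    if outer_iteration < 0:
        raise ValueError("outer_iteration must be >= 0")
    return base + MAX_ERROR_STEP * outer_iteration


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def _components_over_rows(vertices: list, pairs) -> list:
    """Connected components of ``vertices`` under the given (i, j) edges."""
    idx = {v: k for k, v in enumerate(vertices)}
    uf = _UnionFind(len(vertices))
    for i, j in pairs:
        uf.union(idx[i], idx[j])
    groups: dict = {}
    for v in vertices:
        groups.setdefault(uf.find(idx[v]), []).append(v)
    comps = [sorted(g, key=str) for g in groups.values()]
    comps.sort(key=lambda c: str(c[0]))
    return comps


class ContigPositionModel:
    """Weighted linear model for contig start coordinates.

    Parameters
    ----------
    observations : DataFrame with columns ``i, j, Y, w`` (``n``, ``lib``
        optional) — one compressed link cluster per row, each observing
        ``beta_j - beta_i``.
    lengths : mapping contig id -> length in bp (used for gap estimates).
    component : optional explicit vertex list; defaults to the contigs
        appearing in the observations.
    anchor : contig whose position is fixed at 0; defaults to the smallest
        contig id in the component.
    """

    def __init__(self, observations: pd.DataFrame, lengths: dict,
                 component=None, anchor=None):
        self.observations = observations.reset_index(drop=True)
        self.lengths = dict(lengths)
        if component is None:
            component = sorted(set(observations["i"]) | set(observations["j"]),
                               key=str)
        self.component = sorted(component, key=str)
        self.anchor = anchor if anchor is not None else self.component[0]
        if self.anchor not in self.component:
            raise ValueError("anchor must belong to the component")
        self._index = {v: k for k, v in enumerate(self.component)}
        m = len(self.component)
        self._free = [v for v in self.component if v != self.anchor]
        self._free_index = {v: k for k, v in enumerate(self._free)}
        obs = self.observations
        for v in set(obs["i"]) | set(obs["j"]):
            if v not in self._index:
                raise ValueError(f"observation references {v!r} outside the "
                                 "component")
        self._ii = obs["i"].to_numpy()
        self._jj = obs["j"].to_numpy()
        self._y = obs["Y"].to_numpy(dtype=float)
        self._w = obs["w"].to_numpy(dtype=float)
        if np.any(self._w <= 0):
            raise ValueError("weights must be positive")
        self.nobs = len(obs)
        self.n_free = m - 1

    # -- linear algebra -----------------------------------------------------

    def _design(self, mask: np.ndarray) -> sp.csr_matrix:
        rows_i = np.flatnonzero(mask)
        data, rows, cols = [], [], []
        for r, k in enumerate(rows_i):
            for v, sign in ((self._ii[k], -1.0), (self._jj[k], +1.0)):
                if v != self.anchor:
                    rows.append(r)
                    cols.append(self._free_index[v])
                    data.append(sign)
        return sp.csr_matrix((data, (rows, cols)),
                             shape=(len(rows_i), self.n_free))

    def _wls(self, mask: np.ndarray):
        """Weighted LS over the masked rows; residuals over ALL rows.

        Returns (beta over free contigs, residuals e = X beta - Y, XtWX).
        """
        X = self._design(mask)
        w = self._w[mask]
        y = self._y[mask]
        W = sp.diags(w)
        A = (X.T @ W @ X).tocsc()
        rhs = X.T @ (w * y)
        if self.n_free == 0:
            beta = np.empty(0)
        elif self.n_free > CG_CONTIG_LIMIT:
            beta, info = cg(A, rhs, rtol=1e-10, atol=0.0)
            if info != 0:
                beta = spsolve(A, rhs)
        else:
            beta = spsolve(A, rhs)
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        full = self._beta_full(beta)
        pos_i = np.array([full[v] for v in self._ii])
        pos_j = np.array([full[v] for v in self._jj])
        resid = (pos_j - pos_i) - self._y
        return beta, resid, A

    def _beta_full(self, beta_free: np.ndarray) -> dict:
        full = {self.anchor: 0.0}
        for v, k in self._free_index.items():
            full[v] = float(beta_free[k])
        return full

    def _connected(self, mask: np.ndarray):
        pairs = zip(self._ii[mask], self._jj[mask])
        return _components_over_rows(self.component, pairs)

    # -- fitting ------------------------------------------------------------

    def _select(self, resid: np.ndarray, keep: int) -> np.ndarray:
        order = np.argsort(np.abs(resid), kind="stable")
        mask = np.zeros(self.nobs, dtype=bool)
        mask[order[:keep]] = True
        return mask

    def fit_wls(self) -> "ContigPositionResults":
        """Plain weighted least squares over all rows (no trimming)."""
        mask = np.ones(self.nobs, dtype=bool)
        comps = self._connected(mask)
        if len(comps) > 1:
            return ContigPositionResults(self, None, mask, None, 0,
                                         np.inf, split=comps)
        beta, resid, A = self._wls(mask)
        return ContigPositionResults(self, beta, mask, resid, 0, np.inf,
                                     normal_matrix=A)

    def fit(self, max_error: float = DEFAULT_MAX_ERROR
            ) -> "ContigPositionResults":
        """Weighted least trimmed squares (the robust estimator).

        Returns results with ``split`` set (and no estimates) when trimming
        disconnects the component, and ``dissolved=True`` when the rows were
        exhausted before convergence.
        """
        if max_error <= 0:
            raise ValueError("max_error must be > 0")
        n = self.nobs
        mask = np.ones(n, dtype=bool)
        comps = self._connected(mask)
        if len(comps) > 1:
            return ContigPositionResults(self, None, mask, None, 0,
                                         max_error, split=comps)
        t = 0
        while True:
            beta, resid, A = self._wls(mask)
            if np.max(np.abs(resid[mask])) <= max_error:
                return ContigPositionResults(self, beta, mask, resid, t,
                                             max_error, normal_matrix=A)
            keep = n - t
            if keep < max(self.n_free, 1):
                log.warning("WLTS exhausted observations before convergence; "
                            "dissolving component of %d contigs",
                            len(self.component))
                return ContigPositionResults(
                    self, None, mask, resid, t, max_error,
                    split=[[v] for v in self.component], dissolved=True)
            # (n - t) rows with the smallest |residual|, re-selected from the
            # full sample space; stable sort makes ties deterministic.  The
            # select/refit step is iterated to a fixed point (concentration
            # steps) so the kept subset really is the smallest-residual
            # subset under its own fit, not under a stale estimate.
            new_mask = self._select(resid, keep)
            for _ in range(50):
                if len(self._connected(new_mask)) > 1:
                    break
                _beta_c, resid_c, _A = self._wls(new_mask)
                next_mask = self._select(resid_c, keep)
                if np.array_equal(next_mask, new_mask):
                    break
                new_mask = next_mask
            comps = self._connected(new_mask)
            if len(comps) > 1:
                log.info("WLTS trimming disconnected the component into %d "
                         "parts", len(comps))
                return ContigPositionResults(self, None, new_mask, resid, t,
                                             max_error, split=comps)
            mask = new_mask
            t += 1


@dataclass
class ContigPositionResults:
    """Estimates, trimmed-in subset and diagnostics from a position fit."""

    model: ContigPositionModel
    _beta_free: np.ndarray | None
    selected: np.ndarray
    resid: np.ndarray | None
    n_iter: int
    max_error: float
    split: list | None = None
    dissolved: bool = False
    normal_matrix: sp.spmatrix | None = None

    @property
    def converged(self) -> bool:
        return self.split is None and self._beta_free is not None

    @property
    def params(self) -> pd.Series:
        """Contig start coordinates beta (anchor exactly 0)."""
        if not self.converged:
            raise ValueError("no estimates: the component was split")
        full = self.model._beta_full(self._beta_free)
        return pd.Series({v: full[v] for v in self.model.component},
                         name="beta")

    @property
    def removed(self) -> pd.DataFrame:
        """Trimmed-out observations with their residuals."""
        out = self.model.observations[~self.selected].copy()
        if self.resid is not None:
            out["resid"] = self.resid[~self.selected]
        return out

    def scale(self) -> tuple:
        """(weighted residual mean square, dof, model_based flag).

        Weights are ``n/sigma^2`` while the median-CLT error law is
        ``pi*sigma^2/(2n)``, so a perfectly specified model has weighted
        residual variance pi/2; the zero-dof fallback uses that constant
        so model-based standard errors match the median error law.
        """
        nsel = int(self.selected.sum())
        dof = nsel - self.model.n_free
        if dof < 1 or self.resid is None:
            return float(np.pi / 2.0), 0, True
        w = self.model._w[self.selected]
        rss = float(np.sum(w * self.resid[self.selected] ** 2))
        return rss / dof, dof, False

    def cov_params(self) -> pd.DataFrame:
        """Covariance of the free positions: s^2 (X'WX)^-1 over I*."""
        if not self.converged:
            raise ValueError("no estimates: the component was split")
        s2, _dof, _flag = self.scale()
        A = self.normal_matrix
        if A is None:
            raise ValueError("normal matrix unavailable")
        cov = s2 * np.linalg.inv(A.toarray())
        return pd.DataFrame(cov, index=self.model._free,
                            columns=self.model._free)

    def gap_confidence(self, level: float = 0.95) -> pd.DataFrame:
        """Gap estimates with confidence intervals per adjacent contig pair.

        Adjacency follows sorted positions; ``gap = beta_j - beta_i -
        length_i``.  The SE comes from the estimated covariance of
        ``beta_j - beta_i`` with a Student-t quantile at the residual
        degrees of freedom; with zero dof the model-based covariance
        (weights alone) is used with a normal quantile and flagged.
        """
        params = self.params.sort_values(kind="stable")
        cov = self.cov_params()
        _s2, dof, model_based = self.scale()
        z = norm.ppf(0.5 + level / 2.0) if model_based else \
            float(t_dist.ppf(0.5 + level / 2.0, dof))
        rows = []
        ids = list(params.index)
        for left, right in zip(ids[:-1], ids[1:]):
            gap = params[right] - params[left] - self.model.lengths[left]
            var = 0.0
            for v, sgn in ((left, -1.0), (right, 1.0)):
                if v != self.model.anchor:
                    var += cov.loc[v, v]
            if left != self.model.anchor and right != self.model.anchor:
                var -= 2.0 * cov.loc[left, right]
            se = float(np.sqrt(max(var, 0.0)))
            rows.append((left, right, gap, gap - z * se, gap + z * se, se,
                         model_based))
        return pd.DataFrame(rows, columns=["left", "right", "gap", "ci_low",
                                           "ci_high", "se", "model_based"])

    def summary(self, level: float = 0.95) -> str:
        """Human-readable fit summary (positions, trimming, gaps)."""
        lines = ["Contig position estimates (weighted least trimmed squares)",
                 "=" * 60]
        nsel = int(self.selected.sum())
        s2, dof, model_based = self.scale()
        lines.append(f"contigs: {len(self.model.component)}   observations: "
                     f"{self.model.nobs}   selected: {nsel}   "
                     f"iterations: {self.n_iter}")
        lines.append(f"max_error: {self.max_error:g} bp   residual scale^2: "
                     f"{s2:.3f} (dof {dof}"
                     + (", model-based)" if model_based else ")"))
        lines.append("-" * 60)
        lines.append(f"{'contig':<16}{'beta (bp)':>14}")
        for cid, b in self.params.sort_values(kind="stable").items():
            lines.append(f"{str(cid):<16}{b:>14.1f}")
        gaps = self.gap_confidence(level)
        if len(gaps):
            lines.append("-" * 60)
            lines.append(f"{'gap':<26}{'estimate':>10}{'ci':>22}")
            for r in gaps.itertuples(index=False):
                ci = f"[{r.ci_low:.1f}, {r.ci_high:.1f}]"
                lines.append(f"{r.left + ' .. ' + r.right:<26}"
                             f"{r.gap:>10.1f}{ci:>22}")
        return "\n".join(lines)


def exhaustive_wlts_objective(model: ContigPositionModel,
                              max_subsets: int = 1 << 16) -> tuple:
    """Exact minimiser of the trimmed-squares objective by subset enumeration.

    The objective is ``sum_{k in I*} w_k (yhat_k - y_k)^2 + |I \\ I*|``.
    Test oracle only — exponential in the number of rows.
    """
    n = model.nobs
    if 1 << n > max_subsets:
        raise ValueError("too many rows for exhaustive enumeration")
    best = (np.inf, None)
    for bits in range(1, 1 << n):
        mask = np.array([(bits >> k) & 1 for k in range(n)], dtype=bool)
        if len(model._connected(mask)) > 1:
            continue
        _beta, resid, _A = model._wls(mask)
        obj = float(np.sum(model._w[mask] * resid[mask] ** 2)) + (n - mask.sum())
        if obj < best[0] - 1e-12:
            best = (obj, mask)
    return best
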