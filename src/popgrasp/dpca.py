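"""Demixed principal component analysis (dPCA) over task-factor marginalizations.

The trial-averaged population tensor X (units x conditions*time) is split
into additive marginalizations X_phi: the part varying only with time
(condition-independent), with hand, grip or orientation, with each pairwise
interaction, and the residual three-way interaction.  For a balanced
condition grid the marginalizations sum to the per-unit-centered data
exactly and are mutually orthogonal.

For each marginalization dPCA finds a decoder D_phi and encoder F_phi
minimizing ``||X_phi - F_phi D_phi X||^2 + lambda ||F_phi D_phi||^2`` under a
rank constraint.  The ridge solution ``A = X_phi X^T (X X^T + mu I)^-1`` with
``mu = lambda * ||X||_F^2`` (so the dimensionless lambda is comparable across
datasets) is rank-truncated through the SVD of ``A X``; components from all
marginalizations are pooled and the globally strongest (by explained signal
variance) are kept.  With a single marginalization equal to the centered
data and lambda = 0 the procedure reduces exactly to ordinary PCA.

The model/results split follows the statsmodels convention:
``DemixedPCA(data).fit()`` returns a :class:`DemixedPCAResults` carrying
encoders, decoders, component time-courses, variance bookkeeping and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CONDITION_SHAPE, N_CONDITIONS
from .rates import RateTensor

#: marginalization tags; every tag implicitly includes time.  The pure
#: three-way interaction is carried explicitly so the decomposition is exact.
MARGINALIZATION_TAGS = (
    "time",
    "hand",
    "grip",
    "orientation",
    "hand:grip",
    "hand:orientation",
    "grip:orientation",
    "hand:grip:orientation",
)


def _as_tensor5(data) -> tuple[np.ndarray, RateTensor | None]:
    """Coerce input to (units, 2, 2, 5, T)."""
    if isinstance(data, RateTensor):
        rt = data.average_conditions() if data.mode == "single_trial" else data
        return rt.condition_tensor(), rt
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 5:
        return arr, None
    if arr.ndim == 3 and arr.shape[1] == N_CONDITIONS:
        n_u, _, t = arr.shape
        return arr.reshape(n_u, *CONDITION_SHAPE, t), None
    if arr.ndim == 2 and arr.shape[1] % N_CONDITIONS == 0:
        n_u = arr.shape[0]
        t = arr.shape[1] // N_CONDITIONS
        return arr.reshape(n_u, *CONDITION_SHAPE, t), None
    raise ValueError("cannot interpret data as a (units, 2, 2, 5, T) tensor")


def marginalize(data) -> dict[str, np.ndarray]:
    """Decompose per-unit-centered data into its task-factor marginalizations.

    Returns a dict tag -> array of the full tensor shape.  Each X_phi is
    constant over the factors it excludes; the unit grand mean is removed
    first (centering), so ``sum(X_phi) == X - mean`` exactly, and on a
    balanced grid distinct marginalizations are orthogonal.
    """
    X5, _ = _as_tensor5(data)
    M = X5 - X5.mean(axis=(1, 2, 3, 4), keepdims=True)
    a_t = M.mean(axis=(1, 2, 3), keepdims=True)
    a_h = M.mean(axis=(2, 3), keepdims=True) - a_t
    a_g = M.mean(axis=(1, 3), keepdims=True) - a_t
    a_o = M.mean(axis=(1, 2), keepdims=True) - a_t
    a_hg = M.mean(axis=3, keepdims=True) - a_t - a_h - a_g
    a_ho = M.mean(axis=2, keepdims=True) - a_t - a_h - a_o
    a_go = M.mean(axis=1, keepdims=True) - a_t - a_g - a_o
    parts = {
        "time": a_t,
        "hand": a_h,
        "grip": a_g,
        "orientation": a_o,
        "hand:grip": a_hg,
        "hand:orientation": a_ho,
        "grip:orientation": a_go,
    }
    full = np.zeros_like(M)
    out = {}
    for tag, part in parts.items():
        b = np.broadcast_to(part, M.shape).copy()
        out[tag] = b
        full += b
    out["hand:grip:orientation"] = M - full
    return out


@dataclass
class DemixedPCAResults:
    """Fitted dPCA: encoders, decoders and variance bookkeeping.

    Components are sorted by explained signal variance.  ``encoder`` (units
    x K) holds F columns, ``decoder`` (K x units) holds D rows, and
    ``component_tags`` names the marginalization each component belongs to.
    """

    encoder: np.ndarray
    decoder: np.ndarray
    component_tags: np.ndarray
    explained_var: np.ndarray  # fraction of total signal variance, per comp
    cumulative_var: np.ndarray  # joint top-k reconstruction, fraction
    marg_var_share: dict  # tag -> ||X_phi||^2 / sum
    lambda_: float
    unit_means: np.ndarray
    projections: np.ndarray  # (K, conditions*time) component time-courses
    n_time: int
    unit_ids: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.encoder.shape[1]

    def components_for(self, tag: str) -> np.ndarray:
        return np.flatnonzero(self.component_tags == tag)

    def timecourses(self) -> np.ndarray:
        """Component projections shaped (K, 20, T)."""
        return self.projections.reshape(
            self.n_components, N_CONDITIONS, self.n_time
        )

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project (units, anything) data onto the decoders (centered)."""
        return self.decoder @ (X - self.unit_means[:, None])

    def reconstruct(self, component_idx=None) -> np.ndarray:
        """F_k D_k X summed over selected components (centered scale)."""
        if component_idx is None:
            component_idx = np.arange(self.n_components)
        idx = np.asarray(component_idx, dtype=int)
        return self.encoder[:, idx] @ self.projections[idx]

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "marginalization": self.component_tags,
                "explained_var_pct": 100.0 * self.explained_var,
                "cumulative_pct": 100.0 * self.cumulative_var,
            }
        )
        return df


class DemixedPCA:
    """Demixed PCA model over a trial-averaged population tensor.

    Parameters
    ----------
    data : RateTensor or ndarray
        Trial-averaged rates; arrays may be (units, 2, 2, 5, T),
        (units, 20, T) or (units, 20*T).
    marginalizations : sequence of str or None
        Tags to fit; default all eight.  Passing a single tag whose matrix
        equals the centered data makes ``fit(reg=0)`` ordinary PCA.
    """

    def __init__(self, data, marginalizations=None):
        self.X5, self._rate_tensor = _as_tensor5(data)
        self.n_units = self.X5.shape[0]
        self.n_time = self.X5.shape[-1]
        self.tags = tuple(marginalizations or MARGINALIZATION_TAGS)
        for tag in self.tags:
            if tag not in MARGINALIZATION_TAGS and tag != "full":
                raise ValueError(f"unknown marginalization {tag!r}")

    @classmethod
    def from_rate_tensor(cls, tensor: RateTensor, **kw) -> "DemixedPCA":
        return cls(tensor, **kw)

    def fit(
        self,
        n_components: int = 30,
        reg: float = 0.0,
        per_marg_components: int | None = None,
    ) -> DemixedPCAResults:
        """Fit encoders/decoders and keep the strongest components.

        ``reg`` is the dimensionless regularization lambda; the ridge uses
        ``mu = reg * ||X||_F^2``.  ``per_marg_components`` caps how many
        candidates each marginalization contributes before pooling
        (default: ``n_components``).
        """
        if reg < 0:
            raise ValueError("reg must be >= 0")
        n_comp = int(n_components)
        if n_comp < 1 or n_comp > self.n_units:
            raise ValueError("n_components must be in [1, n_units]")
        X5 = self.X5
        unit_means = X5.mean(axis=(1, 2, 3, 4))
        Xc = (X5 - unit_means[:, None, None, None, None]).reshape(self.n_units, -1)
        margs = marginalize(X5)
        marg_mats = {t: m.reshape(self.n_units, -1) for t, m in margs.items()}
        # the pseudo-tag "full" targets the whole centered data (PCA limit)
        marg_mats["full"] = Xc
        total = float(np.sum(Xc * Xc))
        if total == 0:
            raise ValueError("data has zero variance")
        budget = min(
            per_marg_components or n_comp, self.n_units, Xc.shape[1]
        )
        mu = reg * total
        G = Xc @ Xc.T
        Ginv = np.linalg.pinv(G + mu * np.eye(self.n_units))

        enc, dec, tags_out = [], [], []
        for tag in self.tags:
            Xphi = marg_mats[tag]
            A = (Xphi @ Xc.T) @ Ginv
            M = A @ Xc
            if not np.any(M):
                continue
            # left singular vectors of M via the (units x units) Gram matrix
            w, V = np.linalg.eigh(M @ M.T)
            order_w = np.argsort(w)[::-1]
            s = np.sqrt(np.maximum(w[order_w], 0.0))
            U = V[:, order_w]
            q = min(budget, int(np.sum(s > s[0] * 1e-9)))
            for k in range(q):
                f = U[:, k]
                d = f @ A
                enc.append(f)
                dec.append(d)
                tags_out.append(tag)
        if not enc:
            raise ValueError("no components could be extracted")
        F = np.column_stack(enc)
        D = np.vstack(dec)
        P = D @ Xc  # candidate projections
        # explained signal variance of each rank-1 reconstruction
        R = Xc @ P.T  # (units, K)
        ev = (2.0 * np.einsum("uk,uk->k", F, R)
              - np.einsum("uk,uk->k", F, F) * np.einsum("kc,kc->k", P, P)) / total
        order = np.argsort(ev)[::-1][:n_comp]
        F, D, P = F[:, order], D[order], P[order]
        tags_arr = np.asarray(tags_out, dtype=object)[order]
        ev = ev[order]
        # joint cumulative reconstruction quality (always <= the PCA curve)
        cum = np.empty(len(order))
        recon = np.zeros_like(Xc)
        for k in range(len(order)):
            recon += np.outer(F[:, k], P[k])
            cum[k] = 1.0 - float(np.sum((Xc - recon) ** 2)) / total
        marg_tot = {
            tag: float(np.sum(m * m)) for tag, m in margs.items()
        }
        s_all = sum(marg_tot.values())
        shares = {tag: v / s_all for tag, v in marg_tot.items()}
        unit_ids = (
            self._rate_tensor.unit_ids if self._rate_tensor is not None else None
        )
        return DemixedPCAResults(
            encoder=F,
            decoder=D,
            component_tags=tags_arr,
            explained_var=ev,
            cumulative_var=cum,
            marg_var_share=shares,
            lambda_=float(reg),
            unit_means=unit_means,
            projections=P,
            n_time=self.n_time,
            unit_ids=unit_ids,
        )


def pca_cumulative(data, n_components: int) -> np.ndarray:
    """Ordinary-PCA cumulative explained-variance baseline (fractions)."""
    X5, _ = _as_tensor5(data)
    Xc = (X5 - X5.mean(axis=(1, 2, 3, 4), keepdims=True)).reshape(X5.shape[0], -1)
    s = np.linalg.svd(Xc, compute_uv=False)
    v = s**2
    return np.cumsum(v[:n_components]) / v.sum()


def variance_summary(results: DemixedPCAResults, data) -> pd.DataFrame:
    """Per-component variance table with the ordinary-PCA baseline curve."""
    pca = pca_cumulative(data, results.n_components)
    df = results.summary()
    df["pca_cumulative_pct"] = 100.0 * pca[: len(df)]
    return df


def cross_validate_lambda(
    single_trial: RateTensor,
    lambdas,
    n_components: int = 30,
    n_reps: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Choose the regularization lambda by held-out-trial cross-validation.

    In each repetition one random trial per unit and condition is held out;
    the remaining trials are averaged, the model is fitted for every lambda
    on the training average, and the per-marginalization reconstruction
    error of the held-out (marginalized) estimates is scored.  Returns the
    error-minimizing lambda and the error curve.
    """
    lambdas = np.asarray(list(lambdas), dtype=float)
    if lambdas.size < 1:
        raise ValueError("lambda grid is empty")
    if single_trial.mode != "single_trial":
        raise ValueError("cross-validation needs single-trial rates")
    vals = single_trial.values
    conds = single_trial.trial_conditions
    n_units, _, T = vals.shape
    rng = np.random.default_rng(seed)
    errors = np.zeros((n_reps, len(lambdas)))
    for rep in range(n_reps):
        X_train = np.empty((n_units, N_CONDITIONS, T))
        X_test = np.empty((n_units, N_CONDITIONS, T))
        for c in range(N_CONDITIONS):
            idx = np.flatnonzero(conds == c)
            if len(idx) < 2:
                raise ValueError(f"condition {c} needs >= 2 trials")
            for u in range(n_units):
                hold = rng.choice(idx)
                rest = idx[idx != hold]
                X_test[u, c] = vals[u, hold]
                X_train[u, c] = vals[u, rest].mean(axis=0)
        model = DemixedPCA(X_train)
        means = X_train.mean(axis=(1, 2))
        Xt_c = (X_test - means[:, None, None]).reshape(n_units, -1)
        test_margs = marginalize(X_test)
        for li, lam in enumerate(lambdas):
            res = model.fit(n_components=min(n_components, n_units), reg=lam)
            err = 0.0
            for tag in MARGINALIZATION_TAGS:
                idx = res.components_for(tag)
                if len(idx) == 0:
                    recon = 0.0
                else:
                    recon = res.encoder[:, idx] @ (res.decoder[idx] @ Xt_c)
                err += float(
                    np.sum((test_margs[tag].reshape(n_units, -1) - recon) ** 2)
                )
            errors[rep, li] = err
    mean_err = errors.mean(axis=0)
    best = float(lambdas[int(np.argmin(mean_err))])
    table = pd.DataFrame({"lambda": lambdas, "cv_error": mean_err})
    return best, table
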