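"""Banded ridge temporal response functions (TRFs).

A TRF is a linear filter mapping time-lagged stimulus features to a neural
response channel.  With several heterogeneous feature groups (spectrograms,
acoustic edges, phonetic features, onsets) a single ridge penalty is a poor
fit; *banded* ridge regression gives each feature group its own L2 penalty
``lambda_g``, solved exactly by rescaling each column by ``1/sqrt(lambda_g)``
and taking a single SVD of the rescaled design.

Lambdas are tuned once on cross-validated prediction accuracy and then frozen
for every subsequent model (baseline, null, shuffled), and are shared across
electrodes so TRF magnitudes remain comparable between electrodes.  The
tuning schedule mirrors the sequential procedure used with auditory iEEG
data: the first two groups (spectrogram and glimpsed edges) are tuned jointly
on a polar grid (one SVD per lambda *ratio*, with the overall scale swept
cheaply through the singular values), and every later group is tuned one at a
time on a log grid with all earlier lambdas frozen.

Model accuracy is the Fisher-transformed Pearson correlation ``z = atanh(r)``
between predicted and held-out responses under 5-fold cross-validation with
contiguous time blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

#: Regularization values reported for the original two-talker iEEG dataset,
#: loadable in place of tuning (config key ``lambda_source: reference``).
REFERENCE_LAMBDAS: dict[str, float] = {
    "spectrogram": 42.7,
    "glimpsed_edges": 13.5,
    "masked_edges": 10.0,
    "glimpsed_phoneme_onsets": 31.6,
    "masked_phoneme_onsets": 17.8,
    "glimpsed_phonetic": 144.0,
    "masked_phonetic": 215.0,
    "word_onsets": 31.6,
}

DEFAULT_LAGS_MS = (0.0, 500.0)
DISPLAY_LAGS_MS = (-100.0, 600.0)


class RegressorBank:
    """Ordered, named feature groups sharing one time axis.

    Each group is a time x k matrix with an optional frozen regularization
    weight.  Groups are concatenated (in insertion order) into the design.
    """

    def __init__(self, frame_rate_hz: float = 100.0):
        self.frame_rate_hz = frame_rate_hz
        self._groups: dict[str, np.ndarray] = {}
        self.lambdas: dict[str, float | None] = {}

    def add(self, name: str, matrix: np.ndarray, lam: float | None = None) -> "RegressorBank":
        m = np.atleast_2d(np.asarray(matrix, dtype=float))
        if m.shape[0] == 1 and m.shape[1] > 1:
            m = m.T
        if self._groups:
            n = next(iter(self._groups.values())).shape[0]
            if m.shape[0] != n:
                raise ValueError(f"group {name!r} has {m.shape[0]} frames, bank has {n}")
        if lam is not None and lam <= 0:
            raise ValueError("frozen lambda must be positive")
        self._groups[name] = m
        self.lambdas[name] = lam
        return self

    @property
    def names(self) -> list[str]:
        return list(self._groups)

    @property
    def n_frames(self) -> int:
        if not self._groups:
            raise ValueError("empty bank")
        return next(iter(self._groups.values())).shape[0]

    def __contains__(self, name: str) -> bool:
        return name in self._groups

    def __getitem__(self, name: str) -> np.ndarray:
        return self._groups[name]

    def group_sizes(self) -> dict[str, int]:
        return {k: v.shape[1] for k, v in self._groups.items()}

    def subset(self, names: list[str]) -> "RegressorBank":
        sub = RegressorBank(self.frame_rate_hz)
        for n in names:
            sub.add(n, self._groups[n], self.lambdas[n])
        return sub

    def replace(self, name: str, matrix: np.ndarray) -> "RegressorBank":
        """Copy of the bank with one group's matrix swapped (same lambda)."""
        out = RegressorBank(self.frame_rate_hz)
        for n in self.names:
            out.add(n, matrix if n == name else self._groups[n], self.lambdas[n])
        return out

    def stacked(self) -> np.ndarray:
        return np.hstack([self._groups[n] for n in self.names])

    def feature_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for n in self.names:
            k = self._groups[n].shape[1]
            out[n] = slice(start, start + k)
            start += k
        return out


def make_lag_frames(lags_ms: tuple[float, float] = DEFAULT_LAGS_MS,
                    frame_rate_hz: float = 100.0) -> np.ndarray:
    """Integer lag axis in frames covering [lags_ms[0], lags_ms[1]] inclusive."""
    lo = int(round(lags_ms[0] * frame_rate_hz / 1000.0))
    hi = int(round(lags_ms[1] * frame_rate_hz / 1000.0))
    return np.arange(lo, hi + 1)


def build_lagged_design(features: np.ndarray, lag_frames: np.ndarray) -> np.ndarray:
    """Time x (features * lags) design of delayed feature copies.

    Column order is feature-major, lag-minor: for feature ``f`` and lag
    ``l`` (in frames), column ``f * n_lags + i_l`` at row ``t`` holds
    ``features[t - l, f]``; out-of-range samples are zero.  Negative lags
    anticipate the feature.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    if x.size == 0:
        raise ValueError("empty feature matrix")
    n, k = x.shape
    lags = np.asarray(lag_frames, dtype=int)
    out = np.zeros((n, k * lags.size))
    for f in range(k):
        for i, l in enumerate(lags):
            col = f * lags.size + i
            if l >= 0:
                out[l:, col] = x[: n - l, f] if l < n else 0.0
            else:
                out[: n + l, col] = x[-l:, f]
    return out


def fit_banded_ridge(design: np.ndarray, response: np.ndarray,
                     col_lambdas: np.ndarray) -> np.ndarray:
    """Exact banded-ridge minimizer via column rescaling and a single SVD.

    Minimizes ``||y - Xw||^2 + w' diag(col_lambdas) w`` for every response
    column at once (mass-univariate: the design is shared across electrodes).
    """
    X = np.asarray(design, dtype=float)
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    lam = np.asarray(col_lambdas, dtype=float)
    if lam.size != X.shape[1]:
        raise ValueError("need one lambda per design column")
    if np.any(lam <= 0):
        raise ValueError("lambdas must be positive")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("design/response must be finite")
    d = 1.0 / np.sqrt(lam)
    U, s, Vt = np.linalg.svd(X * d, full_matrices=False)
    shrink = s / (s**2 + 1.0)
    w = Vt.T @ (shrink[:, None] * (U.T @ Y))
    return d[:, None] * w


def expand_group_lambdas(bank: RegressorBank, lag_frames: np.ndarray,
                         lambdas: dict[str, float] | None = None) -> np.ndarray:
    """Per-column lambda vector for the lagged design of a bank."""
    lams = []
    for name in bank.names:
        lam = (lambdas or {}).get(name, bank.lambdas[name])
        if lam is None:
            raise ValueError(f"group {name!r} has no lambda")
        lams.append(np.full(bank[name].shape[1] * lag_frames.size, float(lam)))
    return np.concatenate(lams)


@dataclass
class TRFFit:
    """Fitted TRF weights and cross-validated prediction accuracy.

    weights are indexed (lag, feature, electrode) in the *original* feature
    units (the internal column standardization is undone), so ground-truth
    filters and fitted filters are directly comparable.
    """

    weights: np.ndarray                     # lags x features x electrodes
    lag_frames: np.ndarray
    frame_rate_hz: float
    feature_slices: dict[str, slice]
    lambdas: dict[str, float]
    cv_z: np.ndarray | None = None          # electrodes x folds (NaN = undefined fold)

    @property
    def lag_ms(self) -> np.ndarray:
        return self.lag_frames * 1000.0 / self.frame_rate_hz

    @property
    def mean_z(self) -> np.ndarray:
        if self.cv_z is None:
            raise ValueError("fit has no cross-validated scores")
        return np.nanmean(self.cv_z, axis=1)

    def group_weights(self, name: str) -> np.ndarray:
        """lags x k_g x electrodes weight block for one feature group."""
        return self.weights[:, self.feature_slices[name], :]


def contiguous_folds(n_frames: int, n_folds: int) -> list[tuple[int, int]]:
    """Split the time axis into ``n_folds`` contiguous blocks."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    edges = np.linspace(0, n_frames, n_folds + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_folds)]


def _fisher_z(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-column Fisher z of the Pearson correlation; NaN when degenerate."""
    p = pred - pred.mean(axis=0)
    t = truth - truth.mean(axis=0)
    denom = np.sqrt((p**2).sum(axis=0) * (t**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (p * t).sum(axis=0) / denom
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    r[denom == 0] = np.nan
    return np.arctanh(r)


class CVRidge:
    """Cross-validation engine for banded ridge over a fixed bank and folds.

    Precomputes, per fold, the standardized lagged design, its Gram matrix,
    and the design-response cross-product; any subset of groups with any
    lambdas can then be evaluated cheaply (the sub-Gram is a submatrix).
    Solutions use the normal equations, which coincide with the SVD solution
    of :func:`fit_banded_ridge`.

    Fold boundaries leak information through lagged feature copies, so test
    frames within one lag span of a fold edge are excluded from scoring.
    """

    def __init__(self, bank: RegressorBank, responses: np.ndarray,
                 lag_frames: np.ndarray | None = None, n_folds: int = 5):
        self.bank = bank
        self.lag_frames = (make_lag_frames(frame_rate_hz=bank.frame_rate_hz)
                           if lag_frames is None else np.asarray(lag_frames, int))
        Y = np.asarray(responses, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != bank.n_frames:
            Y = Y.T
        if Y.shape[0] != bank.n_frames:
            raise ValueError("responses do not align with the bank's time axis")
        self.Y = Y
        n = bank.n_frames
        self.folds = contiguous_folds(n, n_folds)
        span = int(np.max(np.abs(self.lag_frames)))
        feats = bank.stacked()
        nl = self.lag_frames.size
        # constant feature columns carry no information; drop them up front
        active = feats.std(axis=0) > 0
        sizes = bank.group_sizes()
        self.col_slices: dict[str, slice] = {}
        start_full, start_red = 0, 0
        for name in bank.names:
            k_full = sizes[name]
            k_red = int(active[start_full:start_full + k_full].sum())
            self.col_slices[name] = slice(start_red * nl, (start_red + k_red) * nl)
            start_full += k_full
            start_red += k_red
        feats = feats[:, active]
        self._fold_data = []
        design = None
        for (a, b) in self.folds:
            train_rows = np.ones(n, dtype=bool)
            train_rows[a:b] = False
            mu = feats[train_rows].mean(axis=0)
            sd = feats[train_rows].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            del design  # free the previous fold's design before rebuilding
            design = build_lagged_design((feats - mu) / sd, self.lag_frames)
            # train rows are the two contiguous chunks around the test block,
            # so Gram and cross-products accumulate from views (no copy)
            X1, X2 = design[:a], design[b:]
            Y1, Y2 = self.Y[:a], self.Y[b:]
            ymu = self.Y[train_rows].mean(axis=0)
            G = X1.T @ X1
            G += X2.T @ X2
            c = X1.T @ (Y1 - ymu) + X2.T @ (Y2 - ymu)
            lo, hi = a + span, max(a + span, b - span)
            self._fold_data.append({
                "G": G,
                "c": c,
                "Xte": design[lo:hi].copy(),
                "yte": self.Y[lo:hi] - ymu,
                "sd": sd,
                "mu": mu,
            })
        del design

    def _cols(self, names: list[str]) -> np.ndarray:
        cols = np.concatenate([np.arange(s.start, s.stop) for n in names
                               for s in [self.col_slices[n]]])
        if cols.size == 0:
            raise ValueError("model has no active regressor columns")
        return cols

    def _col_lambdas(self, names: list[str], lambdas: dict[str, float]) -> np.ndarray:
        nl = self.lag_frames.size
        return np.concatenate([
            np.full((self.col_slices[n].stop - self.col_slices[n].start), lambdas[n])
            for n in names
        ])

    def evaluate(self, names: list[str] | None = None,
                 lambdas: dict[str, float] | None = None) -> np.ndarray:
        """Per-electrode, per-fold Fisher z for a model on a subset of groups."""
        names = names or self.bank.names
        lambdas = self._resolve(names, lambdas)
        cols = self._cols(names)
        d = 1.0 / np.sqrt(self._col_lambdas(names, lambdas))
        zs = []
        for fd in self._fold_data:
            G = fd["G"][np.ix_(cols, cols)]
            A = G * d[:, None] * d[None, :]
            A[np.diag_indices_from(A)] += 1.0
            v = linalg.cho_solve(linalg.cho_factor(A, lower=True),
                                 d[:, None] * fd["c"][cols])
            w = d[:, None] * v
            zs.append(_fisher_z(fd["Xte"][:, cols] @ w, fd["yte"]))
        return np.column_stack(zs)

    def mean_z(self, names: list[str] | None = None,
               lambdas: dict[str, float] | None = None) -> float:
        return float(np.nanmean(self.evaluate(names, lambdas)))

    def _resolve(self, names: list[str],
                 lambdas: dict[str, float] | None) -> dict[str, float]:
        out = {}
        for n in names:
            lam = (lambdas or {}).get(n, self.bank.lambdas[n])
            if lam is None:
                raise ValueError(f"group {n!r} has no lambda (tune or freeze first)")
            out[n] = float(lam)
        return out

    def _eig_sweep(self, names: list[str], unit_lambdas: dict[str, float],
                   radii: np.ndarray) -> np.ndarray:
        """Mean CV z for lambda = radius * unit_lambdas, swept over radii.

        One eigendecomposition per fold; the radius only rescales the
        eigenvalue shrinkage, so the sweep costs a matrix product per radius.
        """
        cols = self._cols(names)
        d = 1.0 / np.sqrt(self._col_lambdas(names, unit_lambdas))
        acc = np.zeros(radii.size)
        cnt = np.zeros(radii.size)
        for fd in self._fold_data:
            G = fd["G"][np.ix_(cols, cols)]
            A = G * d[:, None] * d[None, :]
            evals, Q = np.linalg.eigh(A)
            rhs = Q.T @ (d[:, None] * fd["c"][cols])
            XteQ = (fd["Xte"][:, cols] * d[None, :]) @ Q
            for i, r in enumerate(radii):
                w = rhs / (evals + r)[:, None]
                z = _fisher_z(XteQ @ w, fd["yte"])
                acc[i] += np.nansum(z)
                cnt[i] += np.sum(~np.isnan(z))
        return acc / np.maximum(cnt, 1)


def crossval_predict(bank: RegressorBank, responses: np.ndarray,
                     lambdas: dict[str, float] | None = None,
                     lag_frames: np.ndarray | None = None,
                     n_folds: int = 5) -> np.ndarray:
    """Electrodes x folds Fisher-z prediction accuracy (contiguous folds)."""
    return CVRidge(bank, responses, lag_frames, n_folds).evaluate(lambdas=lambdas)


def fit_trf(bank: RegressorBank, responses: np.ndarray,
            lambdas: dict[str, float] | None = None,
            lag_frames: np.ndarray | None = None,
            n_folds: int | None = 5) -> TRFFit:
    """Fit TRF weights on all data; optionally attach cross-validated scores.

    Features are z-scored (full-data statistics) before lagging and the
    weights are mapped back to original feature units.
    """
    if lag_frames is None:
        lag_frames = make_lag_frames(frame_rate_hz=bank.frame_rate_hz)
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != bank.n_frames:
        Y = Y.T
    feats = bank.stacked()
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    design = build_lagged_design((feats - mu) / sd, lag_frames)
    lams = {}
    for n in bank.names:
        lam = (lambdas or {}).get(n, bank.lambdas[n])
        if lam is None:
            raise ValueError(f"group {n!r} has no lambda")
        lams[n] = float(lam)
    col_lams = expand_group_lambdas(bank, lag_frames, lams)
    Yc = Y - Y.mean(axis=0)
    if design.shape[0] > 3 * design.shape[1]:
        # tall problem: the normal-equation solve is much cheaper than the
        # SVD and yields the identical minimizer
        d = 1.0 / np.sqrt(col_lams)
        A = (design.T @ design) * d[:, None] * d[None, :]
        A[np.diag_indices_from(A)] += 1.0
        W = d[:, None] * linalg.cho_solve(
            linalg.cho_factor(A, lower=True), d[:, None] * (design.T @ Yc))
    else:
        W = fit_banded_ridge(design, Yc, col_lams)
    nl = lag_frames.size
    n_feat = feats.shape[1]
    # undo standardization: column for (feature f, lag l) was divided by sd[f]
    W = W.reshape(n_feat, nl, -1) / sd[:, None, None]
    weights = np.transpose(W, (1, 0, 2))  # lags x features x electrodes
    cv_z = None
    if n_folds is not None:
        cv_z = CVRidge(bank, Y, lag_frames, n_folds).evaluate(lambdas=lams)
    return TRFFit(weights, lag_frames, bank.frame_rate_hz,
                  bank.feature_slices(), lams, cv_z)


def tune_lambdas_sequential(
    bank: RegressorBank,
    responses: np.ndarray,
    lag_frames: np.ndarray | None = None,
    n_folds: int = 5,
    joint_pair: tuple[str, str] | None = None,
    n_angles: int = 17,
    radii: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> dict[str, float]:
    """Sequential lambda schedule: joint polar search, then one-at-a-time.

    Stage 1 jointly tunes the first two groups of the bank (by default) over
    a polar grid: 17 angles parameterize the lambda *ratio*
    ``(cos a, sin a)``, and for each angle the overall scale (radius) is
    swept through the eigenvalues without refactoring.  Stage 2 adds the
    remaining groups one at a time, sweeping each group's lambda over a log
    grid with all earlier lambdas frozen.  Ties break toward larger lambda.
    Deterministic: folds are contiguous and fixed.
    """
    if radii is None:
        radii = np.geomspace(1e-2, 1e5, 15)
    if grid is None:
        grid = np.geomspace(1e-2, 1e5, 25)
    names = bank.names
    if len(names) < 1:
        raise ValueError("empty bank")
    cv = CVRidge(bank, responses, lag_frames, n_folds)
    tuned: dict[str, float] = {}

    if joint_pair is None:
        joint_pair = tuple(names[:2]) if len(names) >= 2 else (names[0],)
    if len(joint_pair) == 2:
        a_name, b_name = joint_pair
        angles = np.linspace(0, np.pi / 2, n_angles + 2)[1:-1]
        best = (-np.inf, None)
        for ang in angles:
            unit = {a_name: float(np.cos(ang)), b_name: float(np.sin(ang))}
            scores = cv._eig_sweep([a_name, b_name], unit, radii)
            for r, sc in zip(radii, scores):
                cand = {a_name: unit[a_name] * r, b_name: unit[b_name] * r}
                if sc > best[0] or (sc == best[0] and best[1] is not None
                                    and sum(cand.values()) > sum(best[1].values())):
                    best = (sc, cand)
        if best[1] is None:
            raise RuntimeError("polar search failed")
        tuned.update(best[1])
        if any(np.isclose(v, r) for v in tuned.values()
               for r in (radii[0], radii[-1])):
            import warnings
            warnings.warn("tuned lambda at grid boundary; optimum may lie outside")
        done = [a_name, b_name]
    else:
        done = []

    for g in names:
        if g in done:
            continue
        model = done + [g]
        best_lam, best_sc = None, -np.inf
        for lam in grid:
            sc = cv.mean_z(model, {**tuned, g: float(lam)})
            if sc > best_sc or (sc == best_sc and best_lam is not None
                                and lam > best_lam):
                best_sc, best_lam = sc, float(lam)
        if np.isclose(best_lam, grid[0]) or np.isclose(best_lam, grid[-1]):
            import warnings
            warnings.warn(f"lambda for {g!r} at grid boundary")
        tuned[g] = best_lam
        done.append(g)
    return tuned
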