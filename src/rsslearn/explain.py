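"""First-order feature attribution by permutation Shapley estimation.

For each sample, features are introduced one at a time in random order
into a background expectation, and each feature is credited with the
marginal change in the mean model prediction.  Averaging these marginal
contributions over permutations estimates the Shapley value of each
binary nucleotide:position feature.  Because every permutation walk
telescopes from the background mean to the model's prediction of the
sample, additivity — base prediction plus the attributions summing to the
prediction — holds exactly for any number of permutations; more
permutations only reduce the variance of the per-feature split.

Antithetic sampling (each drawn permutation is also replayed reversed) is
used to cut variance at no extra cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature attributions plus the base prediction.

    ``values`` is a samples x features DataFrame; ``base_prediction`` is
    the mean model prediction over the background set.  For every row,
    base_prediction + row sum equals the model prediction of that sample.
    """

    values: pd.DataFrame
    base_prediction: float

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def predictions(self) -> pd.Series:
        return self.values.sum(axis=1) + self.base_prediction

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


class PermutationExplainer(BaseEstimator):
    """Permutation-Shapley explainer for a fitted regressor.

    Parameters
    ----------
    model : fitted estimator with ``predict``
    background : DataFrame or array of background samples defining the
        "feature absent" reference distribution (typically the full
        training encoding).
    n_permutations : number of random permutations per sample; each is
        also replayed reversed (antithetic pairs).
    random_state : seed for the permutation draws.
    chunk_size : samples explained per vectorised block (memory knob only;
        does not affect results).
    """

    def __init__(self, model, background, n_permutations: int = 10,
                 random_state: int = 0, chunk_size: int = 512):
        self.model = model
        self.background = background
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.chunk_size = chunk_size

    def _check_columns(self, X: pd.DataFrame) -> list[str]:
        bg_cols = list(pd.DataFrame(self.background).columns)
        x_cols = list(X.columns)
        if bg_cols != x_cols:
            raise ValueError(
                f"feature mismatch between samples and background: "
                f"missing={[c for c in bg_cols if c not in x_cols]}, "
                f"extra={[c for c in x_cols if c not in bg_cols]}"
            )
        return x_cols

    def attributions(self, X: pd.DataFrame, additivity_tol: float = 1e-4
                     ) -> AttributionMatrix:
        """Estimate Shapley attributions for every row of ``X``.

        Raises if per-row additivity is violated beyond ``additivity_tol``
        (which would signal an implementation bug, since additivity is
        exact by construction up to floating point).
        """
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        bg_df = pd.DataFrame(self.background)
        if bg_df.empty:
            raise ValueError("background is empty")
        cols = self._check_columns(X)
        Xa = X.to_numpy(dtype=np.float64)
        bg = bg_df.to_numpy(dtype=np.float64)
        n, F = Xa.shape
        B = bg.shape[0]
        base = float(np.mean(self.model.predict(bg)))
        rng = np.random.default_rng(self.random_state)
        perms = [rng.permutation(F) for _ in range(self.n_permutations)]
        walks = [p for perm in perms for p in (perm, perm[::-1])]

        phi = np.zeros((n, F))
        for start in range(0, n, self.chunk_size):
            xs = Xa[start: start + self.chunk_size]
            m = len(xs)
            for perm in walks:
                big = np.tile(bg, (m, 1))          # (m*B, F) masked matrix
                v_prev = np.full(m, base)
                for f in perm:
                    big[:, f] = np.repeat(xs[:, f], B)
                    v = self.model.predict(big).reshape(m, B).mean(axis=1)
                    phi[start: start + m, f] += v - v_prev
                    v_prev = v
        phi /= len(walks)

        values = pd.DataFrame(phi, index=X.index, columns=cols)
        resid = np.abs(values.to_numpy().sum(axis=1) + base
                       - np.asarray(self.model.predict(X), dtype=float))
        if resid.max() > additivity_tol:
            raise AssertionError(
                f"additivity violated: max residual {resid.max():.3g} > "
                f"{additivity_tol:g}"
            )
        return AttributionMatrix(values=values, base_prediction=base)


def compute_attributions(model, samples: pd.DataFrame, background: pd.DataFrame,
                         seed: int = 0, n_permutations: int = 10,
                         chunk_size: int = 512) -> AttributionMatrix:
    """Functional wrapper over :class:`PermutationExplainer`."""
    return PermutationExplainer(
        model, background, n_permutations=n_permutations,
        random_state=seed, chunk_size=chunk_size,
    ).attributions(samples)


def mean_abs_attribution(matrix: AttributionMatrix) -> pd.DataFrame:
    """Per-feature mean |attribution| (feature importance), descending.

    The global mean over all features and samples is attached in
    ``attrs['global_mean']``.
    """
    if matrix.values.empty:
        raise ValueError("attribution matrix is empty")
    imp = matrix.values.abs().mean(axis=0).sort_values(ascending=False)
    out = imp.rename("mean_abs_attribution").to_frame()
    out.attrs["global_mean"] = float(matrix.values.abs().to_numpy().mean())
    return out


def decision_path(matrix: AttributionMatrix, sample_ids) -> pd.DataFrame:
    """Ordered cumulative attribution traces for selected samples.

    Features are ordered globally by mean |attribution| (descending); each
    trace starts at the base prediction and its running sum ends at the
    model prediction for that sample.  Long-format output: sample, step,
    feature, attribution, cumulative.
    """
    order = matrix.values.abs().mean(axis=0).sort_values(ascending=False).index
    rows = []
    for sid in sample_ids:
        if sid not in matrix.values.index:
            raise KeyError(f"unknown sample id {sid!r}")
        running = matrix.base_prediction
        for step, feat in enumerate(order):
            contrib = float(matrix.values.at[sid, feat])
            running += contrib
            rows.append({"sample": sid, "step": step, "feature": feat,
                         "attribution": contrib, "cumulative": running})
    return pd.DataFrame(rows)
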