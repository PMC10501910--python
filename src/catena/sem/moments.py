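"""Model-implied moments via the reticular path-matrix algebra."""

from __future__ import annotations

import numpy as np

from .model import ModelError, ModelSpec, ParameterTable


def _solve_B(A: np.ndarray) -> np.ndarray:
    nv = A.shape[0]
    try:
        return np.linalg.solve(np.eye(nv) - A, np.eye(nv))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate
        raise ModelError("singular (I - A): directed paths form a cycle") from exc


def implied_moments(
    spec: ModelSpec, params: dict[str, float] | np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-group (mean vector, covariance matrix) over the observed variables.

    ``params`` is either a vector ordered like ``spec.parameter_table().labels``
    or a mapping from label to value covering every free parameter.
    """
    table = spec.parameter_table()
    if isinstance(params, dict):
        missing = [lab for lab in table.labels if lab not in params]
        if missing:
            raise ModelError(f"missing parameter values for {missing}")
        theta = np.array([params[lab] for lab in table.labels], dtype=float)
    else:
        theta = np.asarray(params, dtype=float)
        if theta.shape != (table.n_free(),):
            raise ModelError(
                f"expected {table.n_free()} parameters, got {theta.shape}"
            )
    return [(mu, sigma) for mu, sigma, _, _ in group_moments(table, theta)]


def group_moments(table: ParameterTable, theta: np.ndarray):
    """Yield (mu_obs, sigma_obs, B, mats) per group; B = (I - A)^-1."""
    p = table.n_obs
    out = []
    for mats in table.matrices(theta):
        B = _solve_B(mats["A"])
        C = B @ mats["S"] @ B.T
        mu_full = B @ mats["m"]
        out.append((mu_full[:p], C[:p, :p], B, mats))
    return out
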