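"""Draw observed datasets from a model specification at known parameters."""

from __future__ import annotations

import numpy as np

from .likelihood import ObservedDataset
from .model import ModelSpec
from .moments import group_moments


def simulate_from_spec(
    spec: ModelSpec,
    params: dict[str, float],
    n_per_group: int | dict[str, int],
    rng: np.random.Generator,
) -> ObservedDataset:
    """Multivariate-normal draws from the model-implied moments per group."""
    table = spec.parameter_table()
    missing = [lab for lab in table.labels if lab not in params]
    if missing:
        raise ValueError(f"missing parameter values for {missing}")
    theta = np.array([params[lab] for lab in table.labels], dtype=float)
    blocks, labels = [], []
    for g, (mu, sigma, _, _) in zip(spec.groups, group_moments(table, theta)):
        n = n_per_group[g] if isinstance(n_per_group, dict) else n_per_group
        blocks.append(rng.multivariate_normal(mu, sigma, size=n, method="cholesky"))
        labels += [g] * n
    data = np.vstack(blocks)
    return ObservedDataset(data, spec.observed, np.array(labels), list(spec.groups))


def default_true_params(spec: ModelSpec, rng_or_values=None) -> dict[str, float]:
    """A plausible complete parameter assignment for a spec.

    Loadings 0.8, regressions 0.3, latent variances 1, observed residual
    variances 0.5, covariances 0.3 x sqrt(var product), means 0.  Used as
    the generating truth in recovery simulations; individual labels can
    be overridden by the caller afterwards.
    """
    table = spec.parameter_table()
    values: dict[str, float] = {}
    for label in table.labels:
        gi, mat, i, j = table.placements[label][0]
        lhs = spec.variables[i]
        if mat == "m":
            values[label] = 0.0
        elif mat == "S" and i == j:
            values[label] = 0.5 if lhs in spec.observed else 1.0
        elif mat == "S":
            values[label] = 0.3
        else:
            rhs = spec.variables[j]
            if lhs in spec.latent and rhs in spec.latent:
                # higher-order loading or latent regression
                values[label] = 0.8 if label.startswith(("load", "eq.load")) else 0.3
            else:
                values[label] = 0.8
    return values
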