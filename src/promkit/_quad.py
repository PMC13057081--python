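"""Quadrature grid for latent-trait integrals under a standard-normal prior."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced nodes with N(0,1) prior weights, renormalized to sum to 1.

    Attributes
    ----------
    nodes : (Q,) array of theta values.
    weights : (Q,) array of nonnegative weights summing to 1.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be 1-D arrays of equal length")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / total)

    @property
    def size(self) -> int:
        return self.nodes.size


def default_grid(n_nodes: int = 61, span: float = 6.0) -> QuadratureGrid:
    """61 equally spaced nodes on [-span, span] weighted by the N(0,1) density.

    The span covers the prior's support to ~1e-9 tail mass, so EAP for
    extreme response patterns is not truncated.
    """
    nodes = np.linspace(-span, span, n_nodes)
    weights = norm.pdf(nodes)
    return QuadratureGrid(nodes, weights)
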