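"""Phred qualities, base-call error probabilities and pseudocounts.

The likelihood works on real-valued, pseudocount-augmented count vectors
x-tilde = x + x_P.  Each retained call with error probability e (from its
Phred score) contributes eps + e/3 to *each of the three channels other than
the called base* and nothing to its own channel; eps (default 0.01) models
sequencing-independent noise.  This keeps every channel strictly positive
whenever at least one call was observed, so all Gamma-function evaluations
downstream stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pileup import BaseCountVector

DEFAULT_EPSILON = 0.01


def phred_to_error(q):
    """Base-calling error probability e = 10**(-q/10) for Phred score q."""
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("Phred scores must be >= 0")
    out = 10.0 ** (-q / 10.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class AdjustedCountVector:
    """Pseudocount-augmented real-valued counts for one replicate."""

    adjusted: np.ndarray
    raw: BaseCountVector
    epsilon: float

    @property
    def n(self) -> int:
        return self.raw.n


def pseudocount_vector(call_bases, call_quals, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Pseudocount 4-vector x_P for a stack of calls.

    Accepts parallel arrays of called-base indices (0..3 = A,C,G,T) and
    Phred qualities.  Each call adds eps + e/3 to the three uncalled
    channels; summing the per-call contributions gives
    x_P[k] = sum_l (eps + e_l/3) - sum_{l: base_l = k} (eps + e_l/3).
    """
    bases = np.asarray(call_bases, dtype=np.int64)
    if bases.size == 0:
        return np.zeros(4)
    per_call = epsilon + phred_to_error(call_quals) / 3.0
    per_call = np.atleast_1d(per_call)
    total = per_call.sum()
    own = np.bincount(bases, weights=per_call, minlength=4)
    return total - own


def adjust(
    raw: BaseCountVector,
    epsilon: float = DEFAULT_EPSILON,
    downweight_called: bool = False,
) -> AdjustedCountVector:
    """x-tilde = x + x_P for one replicate.

    With ``downweight_called`` the called channel keeps p = 1 - e per call
    instead of the full integer count; off by default (the pseudocount is
    purely additive).
    """
    xp = pseudocount_vector(raw.call_bases, raw.call_quals, epsilon)
    adjusted = raw.counts.astype(float) + xp
    if downweight_called and raw.call_bases.size:
        e = np.atleast_1d(phred_to_error(raw.call_quals))
        adjusted -= np.bincount(raw.call_bases, weights=e, minlength=4)
    return AdjustedCountVector(adjusted, raw, epsilon)


def adjust_matrix(
    replicates, epsilon: float = DEFAULT_EPSILON, downweight_called: bool = False
) -> np.ndarray:
    """Stack the adjusted vectors of a replicate list into an (N, 4) array."""
    return np.vstack(
        [adjust(r, epsilon, downweight_called).adjusted for r in replicates]
    )
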