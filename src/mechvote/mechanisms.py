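"""The ideological manifold: a two-parameter family of redistribution rules.

A redistribution mechanism (the "referee") maps one round's endowments and
contributions to a fractional split of the multiplied public fund.  The
family mixes an *absolute* component (based on raw coin contributions) with
a *relative* component (based on contribution-to-endowment ratios) through a
parameter ``v``, and within each component mixes the focal player's own
statistic with the mean of the other players' through a parameter ``w``:

    y_i      = v * y_rel_i + (1 - v) * y_abs_i
    y_abs_i  = r * [w * c_i   + (1 - w) * cbar_{-i}]
    y_rel_i  = r * (C / P) * [w * rho_i + (1 - w) * rhobar_{-i}]

with rho_i = c_i / e_i, C = sum(c) and P = sum(rho).  Both components sum to
r*C for every (v, w), so the family conserves the fund exactly.  Three
canonical rules are special points: libertarian (w=1, v=0; each player gets
back r times their own contribution), liberal egalitarian (w=1, v=1; payout
proportional to relative contribution) and strict egalitarian (w=1/k; equal
split regardless of contributions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ManifoldParams",
    "ContributionSummary",
    "RedistributionWeights",
    "Mechanism",
    "ManifoldMechanism",
    "absolute_component",
    "relative_component",
    "manifold_payouts",
    "canonical",
    "equal_split",
    "mechanism_from_id",
    "CANONICAL_NAMES",
]

_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class ManifoldParams:
    """A point (v, w) on the manifold; both parameters live in [0, 1]."""

    v: float
    w: float

    def __post_init__(self):
        if not (0.0 <= self.v <= 1.0):
            raise ValueError(f"v must be in [0, 1], got {self.v}")
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"w must be in [0, 1], got {self.w}")


@dataclass(frozen=True)
class ContributionSummary:
    """Per-round contribution statistics feeding the manifold formulas."""

    endowments: np.ndarray
    contributions: np.ndarray
    rho: np.ndarray          # c_i / e_i
    c_others: np.ndarray     # mean contribution of the other k-1 players
    rho_others: np.ndarray   # mean ratio of the other k-1 players
    total: float             # C = sum c_i
    total_rho: float         # P = sum rho_i

    @classmethod
    def from_arrays(cls, endowments, contributions) -> "ContributionSummary":
        e = np.asarray(endowments, dtype=float)
        c = np.asarray(contributions, dtype=float)
        if e.shape != c.shape:
            raise ValueError("endowments and contributions must have equal length")
        if np.any(e <= 0):
            raise ValueError("endowments must be positive")
        k = e.size
        if k < 2:
            raise ValueError("need at least 2 players")
        rho = c / e
        total = float(c.sum())
        total_rho = float(rho.sum())
        c_others = (total - c) / (k - 1)
        rho_others = (total_rho - rho) / (k - 1)
        return cls(e, c, rho, c_others, rho_others, total, total_rho)


@dataclass(frozen=True)
class RedistributionWeights:
    """Nonnegative per-player fractions of the fund, summing to one."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -_CONSERVATION_TOL):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        object.__setattr__(self, "weights", w)

    def payouts(self, r: float, total_contribution: float) -> np.ndarray:
        return self.weights * r * total_contribution


def absolute_component(summary: ContributionSummary, w: float, r: float) -> np.ndarray:
    """Absolute payout component r*[w*c_i + (1-w)*cbar_{-i}]; sums to r*C."""
    return r * (w * summary.contributions + (1.0 - w) * summary.c_others)


def relative_component(summary: ContributionSummary, w: float, r: float) -> np.ndarray:
    """Relative payout component r*(C/P)*[w*rho_i + (1-w)*rhobar_{-i}].

    An empty fund (C = 0, hence P = 0) short-circuits to zeros, avoiding the
    0/0 in C/P: there is nothing to split.
    """
    if summary.total == 0.0:
        return np.zeros_like(summary.contributions)
    scale = r * summary.total / summary.total_rho
    return scale * (w * summary.rho + (1.0 - w) * summary.rho_others)


def manifold_payouts(endowments, contributions, params: ManifoldParams,
                     r: float) -> tuple[np.ndarray, RedistributionWeights]:
    """Evaluate the manifold mechanism for one round.

    Returns the payout vector and the implied redistribution weights
    (uniform when the fund is empty).
    """
    summary = ContributionSummary.from_arrays(endowments, contributions)
    y_abs = absolute_component(summary, params.w, r)
    y_rel = relative_component(summary, params.w, r)
    y = params.v * y_rel + (1.0 - params.v) * y_abs
    k = summary.endowments.size
    if summary.total == 0.0:
        return np.zeros(k), RedistributionWeights(np.full(k, 1.0 / k))
    weights = y / (r * summary.total)
    # numerical guard: clip tiny negative round-off before the simplex check
    weights = np.clip(weights, 0.0, None)
    weights = weights / weights.sum()
    return y, RedistributionWeights(weights)


class Mechanism:
    """Contract shared by closed-form and neural mechanisms.

    A mechanism exposes ``weights(endowments, contributions)`` returning a
    :class:`RedistributionWeights`; payouts are reconstructed as
    ``weights * r * C``.  Memoryless mechanisms must return identical weights
    for identical single-round inputs.
    """

    id: str = "mechanism"
    memoryless: bool = True

    def weights(self, endowments, contributions) -> RedistributionWeights:
        raise NotImplementedError

    def payouts(self, endowments, contributions, r: float) -> np.ndarray:
        c = np.asarray(contributions, dtype=float)
        return self.weights(endowments, contributions).payouts(r, float(c.sum()))


class ManifoldMechanism(Mechanism):
    """A manifold point wrapped in the common mechanism contract."""

    def __init__(self, params: ManifoldParams, r: float = 1.6, name: str | None = None):
        self.params = params
        self.r = r
        self.id = name or f"manifold:v={params.v:g},w={params.w:g}"
        self.memoryless = True

    def weights(self, endowments, contributions) -> RedistributionWeights:
        _, w = manifold_payouts(endowments, contributions, self.params, self.r)
        return w

    def payouts(self, endowments, contributions, r: float | None = None) -> np.ndarray:
        y, _ = manifold_payouts(endowments, contributions, self.params,
                                self.r if r is None else r)
        return y

    def payouts_batch(self, endowments: np.ndarray, contributions: np.ndarray) -> np.ndarray:
        """Vectorized payouts for a batch of rounds; inputs are [B, k]."""
        e = np.asarray(endowments, dtype=float)
        c = np.asarray(contributions, dtype=float)
        k = e.shape[1]
        v, w, r = self.params.v, self.params.w, self.r
        rho = c / e
        total = c.sum(axis=1, keepdims=True)
        total_rho = rho.sum(axis=1, keepdims=True)
        c_others = (total - c) / (k - 1)
        rho_others = (total_rho - rho) / (k - 1)
        y_abs = r * (w * c + (1.0 - w) * c_others)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(total > 0, r * total / np.where(total_rho > 0, total_rho, 1.0), 0.0)
        y_rel = scale * (w * rho + (1.0 - w) * rho_others)
        return v * y_rel + (1.0 - v) * y_abs


CANONICAL_NAMES = ("strict_egalitarian", "libertarian", "liberal_egalitarian")


def canonical(name: str, k: int = 4) -> ManifoldParams:
    """The manifold coordinates of a canonical mechanism.

    Strict egalitarian is written as w = 1/k; at that point the payout is an
    equal split for every v (v is immaterial there), and v=0 is returned by
    convention.
    """
    if name == "libertarian":
        return ManifoldParams(v=0.0, w=1.0)
    if name == "liberal_egalitarian":
        return ManifoldParams(v=1.0, w=1.0)
    if name == "strict_egalitarian":
        return ManifoldParams(v=0.0, w=1.0 / k)
    raise ValueError(f"unknown canonical mechanism {name!r}; "
                     f"expected one of {CANONICAL_NAMES}")


def equal_split(k: int = 4, r: float = 1.6) -> ManifoldMechanism:
    """The no-referee default: the fund is divided equally (w = 1/k)."""
    return ManifoldMechanism(canonical("strict_egalitarian", k), r=r,
                             name="canonical:strict_egalitarian")


def mechanism_from_id(mech_id: str, r: float = 1.6, k: int = 4) -> Mechanism:
    """Resolve a string mechanism id.

    Supported forms: ``manifold:v=<f>,w=<f>``, ``canonical:<name>`` and
    ``frozen:<path>`` (an exported neural mechanism container).
    """
    if mech_id.startswith("manifold:"):
        kv = dict(part.split("=") for part in mech_id[len("manifold:"):].split(","))
        return ManifoldMechanism(ManifoldParams(v=float(kv["v"]), w=float(kv["w"])), r=r)
    if mech_id.startswith("canonical:"):
        name = mech_id[len("canonical:"):]
        return ManifoldMechanism(canonical(name, k=k), r=r, name=mech_id)
    if mech_id.startswith("frozen:"):
        from .designer import load_frozen

        return load_frozen(mech_id[len("frozen:"):])
    raise ValueError(f"unrecognized mechanism id {mech_id!r}")
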