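"""Shared alignment parameters.

The single knob that matters scientifically is the gap penalty: the cost
charged whenever an alignment column pairs a coordinate triple with a gap.
All column costs are squared distances (Å²), so the gap penalty enters the
sums as a squared cost as well.  The default squared gap cost is 16.0 Å²
(i.e. a gap "costs" as much as a 4 Å mismatch), which sits on the same
scale as the 4.0 Å conserved-core cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AlignParams:
    """Parameters controlling pairwise and multiple structure alignment.

    Attributes
    ----------
    gap_cost_sq:
        Squared cost of a (triple, gap) column in Å².  Default 16.0.
    eta:
        Relative convergence threshold on the sum-of-consensus distance
        between outer iterations.  Default 1e-4.
    max_outer_iters:
        Safety cap on outer refinement iterations.
    inner_tol:
        Absolute tolerance (Å²) on the objective for the interleaved
        transform/consensus inner loop and the pairwise refinement loop.
    max_inner_iters:
        Cap on inner transform/consensus iterations.
    max_pair_iters:
        Cap on the iterated superpose-and-realign loop of the bootstrap
        pairwise aligner.
    seed_windows:
        Gapless seed windows tried by the bootstrap pairwise aligner.
    convergence:
        ``"relative"`` (default) stops when
        ``(SC_prev - SC) / max(SC_prev, 1e-12) < eta``; ``"absolute"``
        stops when ``SC_prev - SC < eta``.
    consensus_rule:
        ``"sc"`` (default) picks centroid vs gap by the full column
        contribution to the SC-distance, which keeps the outer iteration
        monotone; ``"literal"`` drops the gap-row term from the triple
        branch (the textbook two-case comparison).  See
        :func:`mapsci.consensus.consensus_column`.
    """

    gap_cost_sq: float = 16.0
    eta: float = 1e-4
    max_outer_iters: int = 100
    inner_tol: float = 1e-6
    max_inner_iters: int = 100
    max_pair_iters: int = 50
    seed_windows: tuple[str, ...] = ("nterm", "center", "cterm")
    convergence: str = "relative"
    consensus_rule: str = "sc"

    def __post_init__(self) -> None:
        if self.gap_cost_sq <= 0:
            raise ValueError("gap_cost_sq must be positive")
        if not (0 < self.eta < 1):
            raise ValueError("eta must be in (0, 1)")
        if self.convergence not in ("relative", "absolute"):
            raise ValueError(f"unknown convergence mode {self.convergence!r}")
        if self.consensus_rule not in ("sc", "literal"):
            raise ValueError(f"unknown consensus rule {self.consensus_rule!r}")

    @classmethod
    def from_gap_penalty(cls, value: float = 16.0, mode: str = "squared",
                         **kwargs) -> "AlignParams":
        """Build params from a gap penalty given either as a squared cost
        (``mode="squared"``, the default: 16.0 → 16.0 Å² per gap column)
        or as a linear distance rho (``mode="linear"``: rho → rho² Å²).
        """
        if mode == "squared":
            return cls(gap_cost_sq=float(value), **kwargs)
        if mode == "linear":
            return cls(gap_cost_sq=float(value) ** 2, **kwargs)
        raise ValueError(f"unknown gap penalty mode {mode!r}")
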