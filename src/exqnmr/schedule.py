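"""Pulse-sequence bookkeeping for iterated band-selective pure-shift NMR.

Three rules keep the attenuation per iteration consistent and every spectrum
a pure-shift spectrum:

1. **Phase cycling.** The selective 180° pulses are cycled in an alternating
   two-step (x, y) / four-step (x, y, -x, -y) pattern in successive
   iterations, so the minimum cycle length is 2, 8, 16, 64 and 128
   transients for one to five iterations.
2. **J-refocusing delay balance.** Each iteration's J-refocusing element
   contributes tau/2 of J-evolution with a sense that alternates between
   successive identical elements; with an even number of iterations the
   senses would cancel, refocusing J at the start of each chunk and giving
   dispersion-mode chunking sidebands. Doubling the tau/4 delay pair of the
   final element for even n restores a net tau/2 and midpoint refocusing.
   The adjustable padding delays are shrunk to compensate so the total
   pre-acquisition time stays an exact integer multiple of the
   single-iteration duration.
3. **PFG polarity alternation.** Gradient polarity alternates between
   iterations so coherent convective flow phase cancels pairwise: even n is
   fully compensated, odd n retains a single iteration's convection loss.

No vendor pulse-program code is generated; schedules serialise to JSON for
transcription.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

__all__ = [
    "IterationScheduleSpec",
    "phase_cycle",
    "balance_delays",
    "convection_parity",
    "build_schedule",
]

TWO_STEP = ("x", "y")
FOUR_STEP = ("x", "y", "-x", "-y")


@dataclass
class IterationScheduleSpec:
    """Complete bookkeeping for an n-iteration schedule."""

    n: int
    tau: float
    element_duration: float
    phases: list  # per-transient tuples of per-iteration phases
    pfg_polarities: list  # per-iteration +-1
    j_delays: list  # per-iteration (pre, post) delay pair, s
    delta_pad: list  # per-iteration padding delay, s

    def __post_init__(self) -> None:
        for i, pol in enumerate(self.pfg_polarities):
            if pol != (+1 if i % 2 == 0 else -1):
                raise ValueError("PFG polarities must alternate +1, -1, ...")
        for transient in self.phases:
            for ph in transient:
                if ph not in ("x", "y", "-x", "-y"):
                    raise ValueError(f"invalid phase {ph!r}")

    @property
    def total_duration(self) -> float:
        return self.n * self.element_duration + sum(
            pre + post + pad
            for (pre, post), pad in zip(self.j_delays, self.delta_pad)
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "tau": self.tau,
            "element_duration": self.element_duration,
            "phases": [list(t) for t in self.phases],
            "pfg_polarities": list(self.pfg_polarities),
            "j_delays": [list(d) for d in self.j_delays],
            "delta_pad": list(self.delta_pad),
            "total_duration": self.total_duration,
        }


def phase_cycle(n: int) -> list:
    """Per-transient phase assignments for the n selective pulses.

    Iteration i (1-based) uses the two-step list (x, y) when odd and the
    four-step list (x, y, -x, -y) when even; the full cycle is the Cartesian
    product, of length 2^ceil(n/2) * 4^floor(n/2). The cycle counts are
    specified only up to five iterations.
    """
    if not 1 <= n <= 5:
        raise ValueError("phase cycles are defined for 1 <= n <= 5")
    per_iter = [TWO_STEP if (i % 2 == 1) else FOUR_STEP for i in range(1, n + 1)]
    return list(itertools.product(*per_iter))


def convection_parity(n: int) -> str:
    """'compensated' for even n, 'single-iteration-residual' for odd n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return "compensated" if n % 2 == 0 else "single-iteration-residual"


def balance_delays(
    n: int,
    tau: float,
    element_duration: float,
    delta_nominal: float,
) -> tuple:
    """Per-iteration J-refocusing delays and padding.

    Each iteration carries a (tau/4, tau/4) delay pair; for even n the final
    iteration's pair is doubled to (tau/2, tau/2) so the signed J-evolution
    still sums to half a chunk and J is refocused at each chunk midpoint.
    ``delta_nominal`` is the adjustable padding per iteration at n = 1; the
    final iteration's padding shrinks by tau/2 when its pair is doubled so
    that the total pre-acquisition time is exactly
    n x (element_duration + tau/2 + delta_nominal).

    Returns (j_delays, delta_pad). Raises if the padding would go negative,
    reporting the minimal feasible ``delta_nominal``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tau <= 0 or element_duration <= 0 or delta_nominal < 0:
        raise ValueError("timings must be positive (delta_nominal >= 0)")
    j_delays = [(tau / 4.0, tau / 4.0)] * n
    delta_pad = [delta_nominal] * n
    if n % 2 == 0:
        j_delays[-1] = (tau / 2.0, tau / 2.0)
        pad = delta_nominal - tau / 2.0
        if pad < 0:
            raise ValueError(
                "infeasible padding: the doubled delay pair needs "
                f"delta_nominal >= tau/2 = {tau / 2.0:.6g} s "
                f"(got {delta_nominal:.6g} s)"
            )
        delta_pad[-1] = pad
    return j_delays, delta_pad


def _signed_j_evolution(j_delays) -> float:
    """Net signed J-evolution over the schedule (element senses alternate)."""
    total = 0.0
    for i, (pre, post) in enumerate(j_delays):
        sense = +1 if i % 2 == 0 else -1
        total += sense * (pre + post)
    return total


def build_schedule(
    n: int,
    tau: float,
    element_duration: float,
    delta_nominal: float | None = None,
) -> IterationScheduleSpec:
    """Assemble the full schedule: phases, polarities, balanced delays."""
    if delta_nominal is None:
        delta_nominal = tau / 2.0
    j_delays, delta_pad = balance_delays(n, tau, element_duration, delta_nominal)
    return IterationScheduleSpec(
        n=n,
        tau=tau,
        element_duration=element_duration,
        phases=phase_cycle(n),
        pfg_polarities=[+1 if i % 2 == 0 else -1 for i in range(n)],
        j_delays=j_delays,
        delta_pad=delta_pad,
    )
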