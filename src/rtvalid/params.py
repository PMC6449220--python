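"""Parameter containers for the two evidence-accumulation model families.

Two scale conventions for the diffusion coefficient circulate in the
literature: ``s = 1`` and ``s = 0.1``.  They describe the same model up to a
multiplicative rescaling of ``v``, ``a`` (and the variability parameters), so
this package standardises on ``s = 1`` and provides :func:`rescale_diffusion`
to convert between conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


class ParameterError(ValueError):
    """A parameter set violates its domain constraints."""


@dataclass(frozen=True)
class DiffusionParams:
    """One condition's diffusion parameters (stimulus-coded, upper = 'R').

    Parameters
    ----------
    v
        Mean rate of evidence accumulation toward the boundary matching the
        stimulus (evidence units / s).  Interpreted as ease of processing.
    a
        Boundary separation (evidence units).  Interpreted as response caution.
    zr
        Relative starting point, as a fraction of ``a``.  ``zr > 0.5`` biases
        the process toward the upper ('R') boundary.
    ter
        Non-decision time added to the first-passage time (s).
    s
        Within-trial diffusion coefficient (evidence / sqrt(s)); the scale
        parameter of the model.
    sv, szr, st
        Trial-to-trial standard deviation of drift, range of relative start
        point, and range of non-decision time.  All zero gives the simple
        diffusion model exactly.
    """

    v: float
    a: float
    zr: float = 0.5
    ter: float = 0.3
    s: float = 1.0
    sv: float = 0.0
    szr: float = 0.0
    st: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ParameterError(f"boundary separation must be positive, got a={self.a}")
        if not 0.0 < self.zr < 1.0:
            raise ParameterError(f"relative start point must lie in (0, 1), got zr={self.zr}")
        if self.ter < 0:
            raise ParameterError(f"non-decision time must be >= 0, got ter={self.ter}")
        if not self.s > 0:
            raise ParameterError(f"diffusion coefficient must be positive, got s={self.s}")
        if self.sv < 0 or self.szr < 0 or self.st < 0:
            raise ParameterError("variability parameters sv, szr, st must be >= 0")
        if self.szr >= 2.0 * min(self.zr, 1.0 - self.zr):
            raise ParameterError(
                f"szr={self.szr} pushes the start-point range outside (0, 1) for zr={self.zr}"
            )
        if self.st > 2.0 * self.ter:
            raise ParameterError(f"st={self.st} pushes the non-decision-time range below 0")

    @property
    def is_simple(self) -> bool:
        """True when all trial-to-trial variabilities are zero."""
        return self.sv == 0.0 and self.szr == 0.0 and self.st == 0.0


def rescale_diffusion(p: DiffusionParams, s_new: float) -> DiffusionParams:
    """Re-express ``p`` under a different diffusion-scale convention.

    Divides ``v``, ``a``, ``sv`` (and ``s``) by a common factor so that the
    predicted choice-RT distributions are unchanged; ``zr``, ``szr``, ``ter``
    and ``st`` are scale-free.
    """
    if not s_new > 0:
        raise ParameterError("target scale must be positive")
    k = s_new / p.s
    return replace(p, v=p.v * k, a=p.a * k, s=s_new, sv=p.sv * k)


@dataclass(frozen=True)
class LBAParams:
    """One condition's linear-ballistic-accumulator parameters.

    Each response side has one accumulator.  On each trial an accumulator
    starts at a point drawn uniformly from ``[0, A]`` and rises linearly with
    a slope drawn from a normal distribution; the first to reach its
    threshold wins.  ``v_c`` is the mean slope of the accumulator matching
    the stimulus, ``v_e`` of the mismatching one; ``sdrift`` is the shared
    between-trial slope SD.  ``start_bias`` lowers the threshold of the 'R'
    accumulator and raises the 'L' one by the same amount, so positive values
    favour 'R' responses.
    """

    b: float
    A: float
    v_c: float
    v_e: float
    sdrift: float = 1.0
    t0: float = 0.2
    start_bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.A <= self.b:
            raise ParameterError(f"need 0 <= A <= b, got A={self.A}, b={self.b}")
        if not self.sdrift > 0:
            raise ParameterError(f"drift SD must be positive, got sdrift={self.sdrift}")
        if self.t0 < 0:
            raise ParameterError(f"non-decision time must be >= 0, got t0={self.t0}")
        if abs(self.start_bias) >= self.b - self.A:
            raise ParameterError(
                "start_bias must keep both side-specific thresholds above the start range"
            )

    def threshold(self, side_is_upper: bool) -> float:
        """Side-specific threshold: 'R' (upper) is ``b - start_bias``."""
        return self.b - self.start_bias if side_is_upper else self.b + self.start_bias
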