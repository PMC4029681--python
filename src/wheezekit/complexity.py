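"""A-priori operation-count model and execution-efficiency metrics.

The cost of each program block of the four detectors is modeled as a worst
case count of (multiplications, additions), assuming elementary functions are
implemented by standard iterative approximations on a plain fixed-point DSP:
division by Newton-Raphson (``n_it_nr`` iterations), square root by Newton's
algorithm (``n_it_n``), log2/sin/cos/arctg by truncated Taylor series
(``n_it_tl``/``n_it_ts``/``n_it_tc``/``n_it_ta`` terms), and the FFT by
radix-2 decimation in time. Additive constants are omitted; multiplicative
constants are kept. All arithmetic is exact integer arithmetic.

An algorithm's total cost is the sum of the blocks on its decision-tree path
(``algorithm_cost``). A published per-algorithm closed form exists for the
same totals but contains typesetting inconsistencies against its own
per-block constituents; it is preserved verbatim as ``algorithm_cost_printed``
and the differences are enumerated by ``table5_discrepancies`` rather than
silently corrected.

The efficiency metrics divide classification quality (SE/SP/AC in percent) by
the processing duty-cycle D_exec -- the percentage of the inter-segment
interval the processor must spend awake to classify one segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "ComplexityParams",
    "OpCount",
    "CHARACTERISTIC",
    "BLOCKS",
    "ALGORITHM_BLOCKS",
    "block_cost",
    "algorithm_cost",
    "algorithm_cost_printed",
    "table5_discrepancies",
    "efficiency",
]


@dataclass(frozen=True)
class ComplexityParams:
    """Problem sizes and iteration counts entering the cost formulas.

    ``n`` is the FFT length (a power of two), ``n_b`` the analysis-band bin
    count, ``n_p`` the worst-case peak count, ``b_crest``/``b_narrow``/
    ``b_wide`` crest and surrounding bandwidths in bins, ``n_c`` the crest
    count and ``m_cont`` the number of continuity lags.
    """

    n: int = 512
    n_b: int = 57
    n_p: int = 20
    b_crest: int = 6
    n_c: int = 7
    m_cont: int = 4
    b_narrow: int = 8
    b_wide: int = 12
    n_it_nr: int = 3
    n_it_n: int = 5
    n_it_tl: int = 5
    n_it_ts: int = 3
    n_it_tc: int = 3
    n_it_ta: int = 3

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n & (self.n - 1):
            raise ValueError("n must be a power of two")

    @property
    def log2n(self) -> int:
        return self.n.bit_length() - 1

    def with_params(self, **kw) -> "ComplexityParams":
        return replace(self, **kw)


#: The characteristic parameter set used for the headline cost comparison.
CHARACTERISTIC = ComplexityParams()


@dataclass(frozen=True)
class OpCount:
    mults: int
    adds: int

    def __add__(self, other: "OpCount") -> "OpCount":
        return OpCount(self.mults + other.mults, self.adds + other.adds)

    @property
    def total(self) -> int:
        return self.mults + self.adds


def _div(p):  # Newton-Raphson division
    return OpCount(3 * p.n_it_nr, p.n_it_nr)


def _sqrt(p):  # Newton's algorithm
    return OpCount(2 * p.n_it_n, 2 * p.n_it_n)


def _log2(p):  # Taylor series
    return OpCount(p.n_it_tl * (p.n_it_tl + 1) // 2, p.n_it_tl)


def _sin(p):
    return OpCount((2 * p.n_it_ts - 1) ** 2, p.n_it_ts)


def _cos(p):
    return OpCount((2 * p.n_it_tc - 2) * (2 * p.n_it_tc - 1), p.n_it_tc)


def _arctg(p):
    return OpCount((2 * p.n_it_ta - 1) ** 2, p.n_it_ta)


def _windowing(p):  # one multiply per sample by the window
    return OpCount(p.n, 0)


def _stft(p):  # radix-2 decimation-in-time FFT
    return OpCount(2 * p.n * p.log2n, 3 * p.n * p.log2n)


def _power_spectrum(p):  # Re^2 + Im^2 on the band bins only
    return OpCount(2 * p.n_b, p.n_b)


def _amplitude_spectrum(p):  # sqrt per band bin
    return OpCount(2 * p.n_b * p.n_it_n, 2 * p.n_b * p.n_it_n)


def _phase_spectrum(p):  # arctg(Im/Re) per band bin
    return OpCount(
        p.n_b * ((2 * p.n_it_ta - 1) ** 2 + 3 * p.n_it_nr + 1),
        p.n_b * (p.n_it_nr + p.n_it_ta - 1),
    )


def _energy(p):  # band sum plus running min/max bookkeeping
    return OpCount(p.n_b, 3 * p.n_b)


def _tonality(p):
    # per-bin: cos, sin, arctg-scale error, sqrt, division; plus one log2
    mults = (
        p.n_b
        * (
            (2 * p.n_it_tc - 2) * (2 * p.n_it_tc - 1)
            + (2 * p.n_it_ta - 1) ** 2
            + 2 * p.n_it_n
            + 3 * p.n_it_nr
            + 5
        )
        + p.n_it_tl * (p.n_it_tl + 1) // 2
    )
    adds = (
        p.n_b * (p.n_it_tc + p.n_it_ta + 2 * p.n_it_n + p.n_it_nr + 1)
        + p.n_it_nr
        + p.n_it_tl
    )
    return OpCount(mults, adds)


def _peaks(p):  # comparisons counted as additions
    return OpCount(0, 2 * p.n_b + p.n_p**2)


def _entropy(p):
    return OpCount(
        p.n_p * (p.n_it_tl * (p.n_it_tl + 1) + 3) + 3 * p.n_it_nr,
        p.n_p * (2 * (p.n_it_tl - 1) + p.n_it_nr + 1) + p.n_it_nr,
    )


def _crests_moments(p):
    return OpCount(
        p.n_p * (3 * p.b_crest + 2 * p.n_it_n + 2),
        p.n_p * (3 * p.b_crest + 2 * p.n_it_n - 2),
    )


def _crests_energy(p):
    return OpCount(
        p.n_p * (p.b_crest + p.b_narrow + p.b_wide + 2 * (3 * p.n_it_nr + 1)),
        p.n_p * (p.b_crest + p.b_narrow + p.b_wide + 2 * (p.n_it_nr + 1) - 3),
    )


def _continuity(p):
    return OpCount(0, p.m_cont * p.n_c**2 + 3 * p.n_c)


BLOCKS = {
    "division": _div,
    "sqrt": _sqrt,
    "log2": _log2,
    "sin": _sin,
    "cos": _cos,
    "arctg": _arctg,
    "windowing": _windowing,
    "stft": _stft,
    "power_spectrum": _power_spectrum,
    "amplitude_spectrum": _amplitude_spectrum,
    "phase_spectrum": _phase_spectrum,
    "energy": _energy,
    "tonality": _tonality,
    "peaks": _peaks,
    "entropy": _entropy,
    "crests_moments": _crests_moments,
    "crests_energy": _crests_energy,
    "continuity": _continuity,
}

#: decision-tree composition of each algorithm
ALGORITHM_BLOCKS = {
    1: ["windowing", "stft", "power_spectrum", "energy", "peaks", "crests_moments", "continuity"],
    2: ["windowing", "stft", "power_spectrum", "energy", "peaks", "crests_energy", "continuity"],
    3: [
        "windowing",
        "stft",
        "power_spectrum",
        "amplitude_spectrum",
        "phase_spectrum",
        "energy",
        "tonality",
    ],
    4: ["windowing", "stft", "power_spectrum", "energy", "peaks", "entropy"],
}


def block_cost(block: str, params: ComplexityParams = CHARACTERISTIC) -> OpCount:
    """Worst-case (multiplications, additions) of one program block."""
    try:
        fn = BLOCKS[block]
    except KeyError:
        raise ValueError(f"unknown block {block!r}; one of {sorted(BLOCKS)}") from None
    return fn(params)


def algorithm_cost(algorithm: int, params: ComplexityParams = CHARACTERISTIC) -> OpCount:
    """Total per-segment cost: the sum of the algorithm's block costs."""
    if algorithm not in ALGORITHM_BLOCKS:
        raise ValueError("algorithm must be 1, 2, 3 or 4")
    total = OpCount(0, 0)
    for block in ALGORITHM_BLOCKS[algorithm]:
        total = total + block_cost(block, params)
    return total


def algorithm_cost_printed(algorithm: int, params: ComplexityParams = CHARACTERISTIC) -> OpCount:
    """The published closed-form per-algorithm totals, evaluated verbatim.

    Kept for reference; see :func:`table5_discrepancies` for where these rows
    disagree with the sum of their own per-block constituents.
    """
    p = params
    ln = p.log2n
    if algorithm == 1:
        return OpCount(
            p.n * (2 * ln + 1) + 3 * p.n_b + p.n_p * (3 * p.b_crest + 2 * p.n_it_n + 2),
            3 * p.n * ln
            + 6 * p.n_b
            + p.n_p**2
            + p.n_p * (3 * p.b_crest + 2 * p.n_it_n - 2)
            + p.n_c * (p.m_cont + 1),
        )
    if algorithm == 2:
        return OpCount(
            p.n * (2 * ln + 1)
            + 3 * p.n_b
            + p.n_p * (p.b_crest + p.b_narrow + p.b_wide + 6 * p.n_it_nr + 2),
            3 * p.n * ln
            + 6 * p.n_b
            + p.n_p**2
            + p.n_p * (p.b_crest + p.b_narrow + p.b_wide + 2 * (p.n_it_nr + 1) - 3)
            + p.n_c * (p.m_cont + 1),
        )
    if algorithm == 3:
        return OpCount(
            p.n * (2 * ln + 1)
            + p.n_b
            * (
                2 * (2 * p.n_it_ta - 1) ** 2
                + (2 * p.n_it_tc - 2) * (2 * p.n_it_tc - 1)
                + 4 * p.n_it_n
                + 6 * p.n_it_nr
                + 9
            )
            + p.n_it_tl * (p.n_it_tl + 1) // 2,
            3 * p.n * ln
            + p.n_b * (4 * p.n_it_n + p.n_it_tc + p.n_it_ta + p.n_it_nr + 5)
            + p.n_it_nr
            + p.n_it_tl,
        )
    if algorithm == 4:
        return OpCount(
            p.n * (2 * ln + 1)
            + 3 * p.n_b
            + p.n_p * (p.n_it_tl * (p.n_it_tl + 1) + 3)
            + 3 * p.n_it_nr,
            3 * p.n * ln
            + 6 * p.n_b
            + p.n_p**2
            + p.n_p * (2 * (p.n_it_tl - 1) + p.n_it_nr + 1)
            + p.n_it_nr,
        )
    raise ValueError("algorithm must be 1, 2, 3 or 4")


def table5_discrepancies(params: ComplexityParams = CHARACTERISTIC) -> dict[int, dict]:
    """Differences between the printed closed forms and the block-sum totals.

    Known sources: the printed rows write the crest continuity additions as
    N_c(M_cont+1) where the per-block formula is M_cont*N_c^2 + 3*N_c, and the
    tonality-path additions coefficient is inconsistent with its constituents
    (the per-block tonality row also contains a stray token read as 2*N_it_n).
    """
    report = {}
    for alg in (1, 2, 3, 4):
        comp = algorithm_cost(alg, params)
        printed = algorithm_cost_printed(alg, params)
        if comp != printed:
            report[alg] = {
                "compositional": comp,
                "printed": printed,
                "delta_mults": comp.mults - printed.mults,
                "delta_adds": comp.adds - printed.adds,
            }
    return report


@dataclass(frozen=True)
class Efficiency:
    d_exec: float  # duty cycle, percent
    mu_se: float | None
    mu_sp: float | None
    mu_ac: float | None


def efficiency(
    cycles_exec: float,
    cycles_total: float,
    se: float | None = None,
    sp: float | None = None,
    ac: float | None = None,
    duty_decimals: int | None = None,
) -> Efficiency:
    """Duty cycle D_exec = 100 * cycles_exec / cycles_total and mu = metric / D_exec.

    Metrics are in percent. ``duty_decimals`` optionally rounds D_exec before
    the division, reproducing published arithmetic that divides by a duty
    cycle printed to fixed precision.
    """
    if cycles_exec <= 0:
        raise ValueError("cycles_exec must be positive")
    if cycles_exec > cycles_total:
        raise ValueError("cycles_exec cannot exceed cycles_total")
    d = 100.0 * cycles_exec / cycles_total
    if duty_decimals is not None:
        d = round(d, duty_decimals)
    mu = lambda x: None if x is None else x / d  # noqa: E731
    return Efficiency(d_exec=d, mu_se=mu(se), mu_sp=mu(sp), mu_ac=mu(ac))
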