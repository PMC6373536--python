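"""Core domain types for the approach-avoidance diffusion pipeline.

Trial-level data and per-cell summaries travel as :class:`pandas.DataFrame`
objects with fixed column schemas (the idiomatic container for tabular
behavioural data); small parameter bundles and statistical results are
frozen dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TRIAL_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "CELL_COLUMNS",
    "EXPRESSIONS",
    "RESPONSES",
    "GENDERS",
    "MAPPINGS",
    "DiffusionParams",
    "ScenarioConfig",
    "BayesFactorResult",
    "EffectSizeResult",
]

#: Canonical trial CSV schema (one row per trial).
TRIAL_COLUMNS = [
    "participant_id",
    "participant_gender",
    "block",
    "mapping",
    "trial_index",
    "stimulus_id",
    "expression",
    "face_gender",
    "required_response",
    "observed_response",
    "rt_ms",
    "correct",
]

#: Participants CSV schema (questionnaire totals).
PARTICIPANT_COLUMNS = [
    "participant_id",
    "participant_gender",
    "bis",
    "bas",
    "bas_drive",
    "bas_fun",
    "bas_reward",
]

#: Per-participant, per-design-cell summary schema.
CELL_COLUMNS = [
    "participant_id",
    "participant_gender",
    "expression",
    "required_response",
    "face_gender",
    "n_total",
    "n_correct",
    "pc",
    "mrt_s",
    "vrt_s2",
    "median_rt_ms",
    "degenerate",
]

EXPRESSIONS = ("angry", "happy")
RESPONSES = ("push", "pull")
GENDERS = ("female", "male")
#: Response mappings: which expression is pushed.
MAPPINGS = ("push-angry/pull-happy", "push-happy/pull-angry")


@dataclass(frozen=True)
class DiffusionParams:
    """Two-boundary Wiener process parameters with an unbiased start.

    Parameters
    ----------
    v : float
        Drift rate (evidence per second); positive drift favours the
        upper (correct) boundary.
    a : float
        Boundary separation (evidence units), must be positive.
    ter : float
        Non-decision time in seconds (encoding + motor execution).
    s : float
        Within-trial noise scaling (evidence / sqrt(s)); fixes the
        model's arbitrary scale. Default 1.0.

    The starting point is always ``z = a / 2`` (symmetric, unbiased);
    it is exposed as a read-only property and never a free parameter.
    """

    v: float
    a: float
    ter: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if self.s <= 0:
            raise ValueError(f"noise scaling must be positive, got s={self.s}")
        if self.ter < 0:
            raise ValueError(f"non-decision time must be >= 0, got ter={self.ter}")

    @property
    def z(self) -> float:
        """Starting point, fixed at a/2."""
        return self.a / 2.0


@dataclass
class ScenarioConfig:
    """Ground truth driving the synthetic experiment generator.

    ``truth`` maps the 16 design cells
    ``(participant_gender, expression, required_response, face_gender)``
    to condition-mean :class:`DiffusionParams`. Between-participant
    variation is a shared participant intercept (``sd_*``) plus a small
    independent condition-level jitter (``jitter_*``); the intercept
    cancels in within-participant contrasts, the jitter does not.
    """

    n_per_gender: int
    truth: dict[tuple[str, str, str, str], DiffusionParams]
    sd_v: float = 0.55
    sd_a: float = 0.10
    sd_ter: float = 0.040
    jitter_v: float = 0.12
    jitter_a: float = 0.03
    jitter_ter: float = 0.012
    contaminant_rate: float = 0.03
    contaminant_fast_ms: tuple[float, float] = (50.0, 199.0)
    contaminant_slow_ms: tuple[float, float] = (2501.0, 4000.0)
    #: (mean, sd) of the BIS total per gender, truncated to [7, 28].
    bis: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (23.32, 3.09), "male": (19.29, 4.21)}
    )
    #: (mean, sd) of the BAS total per gender (0-3 item scoring, range [0, 39]).
    bas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (12.48, 2.33), "male": (13.30, 2.33)}
    )
    #: seconds of extra non-decision time in the female happy/pull cells per
    #: unit of BIS standardised to 2 SD; emulates the reported damping of the
    #: approach advantage in high-BIS women.
    bis_ter_coupling: float = 0.12
    seed: int = 0
    dt: float = 5e-4

    def validate(self) -> None:
        from itertools import product

        if self.n_per_gender < 1:
            raise ValueError("n_per_gender must be >= 1")
        if not (0.0 <= self.contaminant_rate < 0.1):
            raise ValueError("contaminant_rate must lie in [0, 0.1)")
        missing = [
            key
            for key in product(GENDERS, EXPRESSIONS, RESPONSES, GENDERS)
            if key not in self.truth
        ]
        if missing:
            raise ValueError(f"truth table missing conditions: {missing}")


@dataclass(frozen=True)
class BayesFactorResult:
    """A Bayes factor for one model term, with its Jeffreys evidence band."""

    dv: str
    term: str
    bf10: float
    method: str
    label: str


@dataclass(frozen=True)
class EffectSizeResult:
    """Standardised paired effect size dz with a posterior HDI and paired BF."""

    contrast: str
    dz: float
    hdi_low: float
    hdi_high: float
    bf10: float
    cred: float = 0.95
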