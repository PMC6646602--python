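"""Dyad presets: the ASD child parameterization and two parental strategies.

The child preset encodes three clinically motivated deviations from a
typically developing child: weakened emotional processing and communication
(lower a2, a3, a7), a reduced relatedness concern (c_other = 0.50 instead of
~0.70), and a shift from imitation toward repetition (higher a5, a8; lower
a6, a9).

Parents keep the same agent architecture and add four implicit strategy
mechanisms, none of which requires deliberate planning:

1. *scaffolding* -- the parent's relatedness concern is kept slightly above
   (an estimate of) the child's, within a floor or a band;
2. *selective symmetry* -- the parent's imitation weight a6 depends on the
   child's previous behavior;
3. *selective satiation* -- the parent's realization sensitivity a3 differs
   per concern, biasing drives toward joint play;
4. *selective emotional encouragement* -- positive expressions reward the
   child's other-directed play; negative expressions are suppressed.

Two shipped parent presets differ in their goal: the *play-centered* parent
maximizes joint play (large scaffolding distance, strong selectivity), the
*initiative-centered* parent maximizes child-initiated play (small scaffolding
band, weak selectivity, more room for the child).  The numeric defaults below
are calibration outputs constrained by those qualitative contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import AgentParams, Behavior, ConcernPair

__all__ = [
    "EmotionPolicy",
    "StrategyParams",
    "ParentPreset",
    "DyadPreset",
    "typical_child_preset",
    "asd_child_preset",
    "play_centered_parent",
    "initiative_centered_parent",
    "play_centered_dyad",
    "initiative_centered_dyad",
    "dyad_preset",
    "PRESET_NAMES",
    "apply_scaffolding",
    "effective_a6",
    "apply_emotion_policy",
    "encouragement_term",
]


@dataclass(frozen=True, slots=True)
class EmotionPolicy:
    """Strategy-level filter on the parent's expressed emotions."""

    suppress_negative: bool = False
    positive_only_when_child_other: bool = False
    encouragement_strength: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.encouragement_strength <= 1.0):
            raise ValueError("encouragement_strength must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class StrategyParams:
    """Per-step behavioral strategy of a simulated parent.

    ``symmetry_conditional`` is ``(a6 when the child was other-directed,
    a6 when the child was self-directed)``; ``satiation_bias`` is
    ``(a3_relatedness, a3_autonomy)``; scaffolding uses either a fixed lower
    bound (``scaffold_floor``) or offsets relative to an estimate of the
    child's relatedness concern (``scaffold_band``).
    """

    scaffold_floor: float | None = None
    scaffold_band: tuple[float, float] | None = None
    symmetry_conditional: tuple[float, float] | None = None
    satiation_bias: tuple[float, float] | None = None
    emotion_policy: EmotionPolicy = field(default_factory=EmotionPolicy)
    use_true_child_concern: bool = False

    def __post_init__(self) -> None:
        if self.scaffold_band is not None:
            lo, hi = self.scaffold_band
            if not lo < hi:
                raise ValueError("scaffold_band requires lo_offset < hi_offset")
        if self.symmetry_conditional is not None:
            for v in self.symmetry_conditional:
                if not (0.0 <= v <= 1.0):
                    raise ValueError("conditional a6 values must lie in [0, 1]")
        if self.satiation_bias is not None:
            for v in self.satiation_bias:
                if not (0.0 <= v <= 1.0):
                    raise ValueError("satiation sensitivities must lie in [0, 1]")
        if self.scaffold_floor is not None and not (0.0 <= self.scaffold_floor <= 1.0):
            raise ValueError("scaffold_floor must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class ParentPreset:
    """A parent's agent parameters plus its behavioral strategy."""

    params: AgentParams
    strategy: StrategyParams


@dataclass(frozen=True, slots=True)
class DyadPreset:
    """Child and parent parameterizations forming one simulated dyad."""

    child: AgentParams
    parent: AgentParams
    parent_strategy: StrategyParams
    label: str = "custom"


def typical_child_preset() -> AgentParams:
    """Reference parameterization of a typically developing child.

    Relatedness-dominant concerns (c_other = 0.70) with balanced continuity
    and symmetry; serves as the contrast class for the ASD preset.
    """
    return AgentParams(
        a1=0.004,
        a2=0.010,
        a3=0.60,
        a4=0.25,
        a5=0.35,
        a6=0.50,
        a7=0.50,
        a8=0.30,
        a9=0.40,
        baseline=0.25,
        c_other_initial=0.70,
    )


def asd_child_preset() -> AgentParams:
    """Child with severe ASD: the shared child of both shipped dyads.

    Relative to :func:`typical_child_preset`: balanced instead of
    relatedness-dominant concerns (c_other = 0.50), weakened emotional
    processing and communication (lower a2, a3, a7), stronger behavioral and
    emotional continuity (higher a5, a8) and weaker symmetry (lower a6, a9).
    """
    return AgentParams(
        a1=0.004,
        a2=0.002,
        a3=0.088,
        a4=0.787,
        a5=1.0,
        a6=0.0,
        a7=0.15,
        a8=0.55,
        a9=0.08,
        baseline=0.073,
        c_other_initial=0.50,
    )


def play_centered_parent() -> ParentPreset:
    """Parent maximizing joint play.

    Large scaffolding distance (p_other starts at 0.65, floored at the child's
    initial concern 0.50), strong selective symmetry toward joint play, much
    slower satiation for relatedness than autonomy, and strictly selective
    positive encouragement (never negative, positive only while the child is
    other-directed).
    """
    params = AgentParams(
        a1=0.040,
        a2=0.002,
        a3=0.40,
        a4=0.0,
        a5=0.0,
        a6=0.50,
        a7=0.40,
        a8=0.25,
        a9=0.15,
        baseline=0.559,
        c_other_initial=0.65,
    )
    strategy = StrategyParams(
        scaffold_floor=0.50,
        symmetry_conditional=(0.859, 0.0),
        satiation_bias=(0.116, 0.704),
        emotion_policy=EmotionPolicy(
            suppress_negative=True,
            positive_only_when_child_other=True,
            encouragement_strength=1.0,
        ),
    )
    return ParentPreset(params=params, strategy=strategy)


def initiative_centered_parent() -> ParentPreset:
    """Parent maximizing child-initiated play.

    Small scaffolding band (p_other starts at 0.55 and tracks the estimated
    child concern within (+0.01, +0.15)), fairly strong but only slightly
    selective symmetry, mildly biased satiation, limited selective
    encouragement, and no negative expressions.
    """
    params = AgentParams(
        a1=0.020,
        a2=0.002,
        a3=0.45,
        a4=0.205,
        a5=0.733,
        a6=0.35,
        a7=0.40,
        a8=0.25,
        a9=0.15,
        baseline=0.529,
        c_other_initial=0.55,
    )
    strategy = StrategyParams(
        scaffold_band=(0.01, 0.15),
        symmetry_conditional=(0.396, 0.30),
        satiation_bias=(0.564, 0.797),
        emotion_policy=EmotionPolicy(
            suppress_negative=True,
            positive_only_when_child_other=False,
            encouragement_strength=0.32,
        ),
    )
    return ParentPreset(params=params, strategy=strategy)


def play_centered_dyad() -> DyadPreset:
    """ASD child paired with the play-centered parent."""
    parent = play_centered_parent()
    return DyadPreset(
        child=asd_child_preset(),
        parent=parent.params,
        parent_strategy=parent.strategy,
        label="play_centered",
    )


def initiative_centered_dyad() -> DyadPreset:
    """ASD child paired with the initiative-centered parent."""
    parent = initiative_centered_parent()
    return DyadPreset(
        child=asd_child_preset(),
        parent=parent.params,
        parent_strategy=parent.strategy,
        label="initiative_centered",
    )


_DYAD_FACTORIES = {
    "play_centered": play_centered_dyad,
    "initiative_centered": initiative_centered_dyad,
}

PRESET_NAMES = tuple(_DYAD_FACTORIES)


def dyad_preset(name: str) -> DyadPreset:
    """Look up a shipped dyad preset by name."""
    try:
        return _DYAD_FACTORIES[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


def apply_scaffolding(
    parent_concerns: ConcernPair,
    child_reference: float,
    strategy: StrategyParams,
) -> ConcernPair:
    """Clip the parent's relatedness concern to the strategy's scaffold region.

    With a band set, p_other is clipped to
    ``[max(floor, ref + lo_offset), min(1, ref + hi_offset)]``; with only a
    floor it is clipped from below.  The pair is renormalized after clipping.

    A band pushed past the unit boundary by a high reference saturates at 1
    (the parent cannot be more than fully relatedness-concerned); an interval
    emptied by the *floor* signals a misconfiguration and raises.
    """
    if not (0.0 <= child_reference <= 1.0):
        raise ValueError("child_reference must lie in [0, 1]")
    p_other = parent_concerns.c_other
    if strategy.scaffold_band is not None:
        lo_off, hi_off = strategy.scaffold_band
        lo = child_reference + lo_off
        hi = min(1.0, child_reference + hi_off)
        if strategy.scaffold_floor is not None:
            if strategy.scaffold_floor > hi:
                raise ValueError(
                    f"empty scaffolding interval: floor {strategy.scaffold_floor} "
                    f"exceeds upper bound {hi} for reference {child_reference}"
                )
            lo = max(lo, strategy.scaffold_floor)
        lo = min(lo, hi)  # band saturated against the unit boundary
        p_other = min(hi, max(lo, p_other))
    elif strategy.scaffold_floor is not None:
        p_other = max(strategy.scaffold_floor, p_other)
    return ConcernPair.from_other(p_other)


def effective_a6(
    strategy: StrategyParams, child_prev: Behavior, default: float
) -> float:
    """Symmetry weight for this step under conditional (selective) symmetry."""
    if strategy.symmetry_conditional is None:
        return default
    when_other, when_self = strategy.symmetry_conditional
    return when_other if child_prev is Behavior.OTHER_DIRECTED else when_self


def apply_emotion_policy(
    emotion: int, child_prev: Behavior, policy: EmotionPolicy
) -> int:
    """Filter a chosen expression through the parent's emotion policy.

    Withheld expressions become neutral (never negative): suppression of
    negative affect, and withholding of positive affect during the child's
    self-directed play under the selective policy.
    """
    if emotion == -1 and policy.suppress_negative:
        return 0
    if (
        emotion == 1
        and policy.positive_only_when_child_other
        and child_prev is Behavior.SELF_DIRECTED
    ):
        return 0
    return emotion


def encouragement_term(policy: EmotionPolicy, child_prev: Behavior) -> float:
    """Extra latent affect rewarding the child's other-directed play."""
    if child_prev is Behavior.OTHER_DIRECTED:
        return policy.encouragement_strength
    return 0.0
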