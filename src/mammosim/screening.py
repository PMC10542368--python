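"""The mammogram reading pathway: double reading, arbitration, recall.

Each attended screen is read independently by two readers (two humans under
standard practice, one human plus the AI system in the intervention arm).
Concordant calls stand; discordant calls go to a single arbitration reader;
an abnormal final call triggers recall to triple assessment, whose biopsy is
treated as a perfect classifier, so every recall resolves to the truth
(true positive or false positive).

Reader sensitivity is multiplied by a breast-density (VDG) penalty;
specificity is density-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NORMAL, RECALL = "normal", "recall"


@dataclass(frozen=True)
class ReaderProfile:
    """Sensitivity/specificity of one reader (human, AI, arbitration, biopsy)."""

    sensitivity: float
    specificity: float
    label: str = "reader"

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError(f"{self.label}: sensitivity/specificity must be in [0, 1]")


@dataclass(frozen=True)
class ScreeningPolicy:
    """Invitation schedule of the programme (triennial, ages 50-70)."""

    start_age: float = 50.0
    end_age: float = 70.0
    interval: float = 3.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")


@dataclass(frozen=True)
class EpisodeOutcome:
    """Everything that happened in one screening episode."""

    attended: bool
    reads: tuple[bool, bool] | None = None  # per-reader abnormal calls
    discordant: bool = False
    arbitrated: bool = False
    final_call: str = NORMAL
    recall_result: str | None = None  # "TP" or "FP" when recalled
    classification: str = "not-applicable"  # TP / FP / TN / FN

    def __post_init__(self) -> None:
        if self.discordant and not self.arbitrated:
            raise ValueError("discordant episodes must be arbitrated")
        if (self.final_call == RECALL) != (self.recall_result is not None):
            raise ValueError("recall_result set iff final call is recall")


def read_calls_from_uniforms(
    cancer_present: np.ndarray,
    reader: ReaderProfile,
    density_multiplier: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Deterministic core of a single read: abnormal-call indicator per woman.

    With cancer the abnormal probability is sensitivity x density multiplier;
    without, it is 1 - specificity (density does not affect specificity).
    """
    p_abnormal = np.where(
        cancer_present,
        reader.sensitivity * density_multiplier,
        1.0 - reader.specificity,
    )
    return u < p_abnormal


def single_read(
    cancer_present: bool,
    reader: ReaderProfile,
    density_multiplier: float,
    rng: np.random.Generator,
) -> bool:
    """One reader's call; ``True`` means abnormal (positive)."""
    if not 0.0 < density_multiplier <= 1.0:
        raise ValueError("density_multiplier must be in (0, 1]")
    return bool(
        read_calls_from_uniforms(
            np.asarray([cancer_present]),
            reader,
            np.asarray([density_multiplier]),
            rng.random(1),
        )[0]
    )


def episode_calls(
    cancer_present: np.ndarray,
    r1: ReaderProfile,
    r2: ReaderProfile,
    arbitration: ReaderProfile,
    density_multiplier: np.ndarray,
    u1: np.ndarray,
    u2: np.ndarray,
    u_arb: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vectorised reading pathway for a batch of attended episodes.

    Returns boolean arrays: ``pos1``, ``pos2``, ``discordant``, ``arbitrated``
    (alias of discordant), ``recall`` (final abnormal call).  Recall resolves
    to truth downstream because the biopsy is perfect.
    """
    pos1 = read_calls_from_uniforms(cancer_present, r1, density_multiplier, u1)
    pos2 = read_calls_from_uniforms(cancer_present, r2, density_multiplier, u2)
    discordant = pos1 != pos2
    # arbitration reviews the discordant study with both first reads in hand;
    # its profile is applied unpenalised by density
    arb_pos = read_calls_from_uniforms(
        cancer_present, arbitration, np.ones_like(density_multiplier, dtype=float), u_arb
    )
    recall = np.where(discordant, arb_pos, pos1 & pos2)
    return {
        "pos1": pos1,
        "pos2": pos2,
        "discordant": discordant,
        "arbitrated": discordant,
        "recall": recall,
    }


def screening_episode(
    cancer_present: bool,
    r1: ReaderProfile,
    r2: ReaderProfile,
    arbitration: ReaderProfile,
    density_multiplier: float,
    rng: np.random.Generator,
    attended: bool = True,
) -> EpisodeOutcome:
    """One woman's screening episode through the Fig.-style pathway."""
    if not attended:
        return EpisodeOutcome(attended=False)
    present = np.asarray([cancer_present])
    mult = np.asarray([density_multiplier])
    calls = episode_calls(
        present, r1, r2, arbitration, mult, rng.random(1), rng.random(1), rng.random(1)
    )
    recall = bool(calls["recall"][0])
    if recall:
        recall_result = "TP" if cancer_present else "FP"
        classification = recall_result
    else:
        recall_result = None
        classification = "FN" if cancer_present else "TN"
    return EpisodeOutcome(
        attended=True,
        reads=(bool(calls["pos1"][0]), bool(calls["pos2"][0])),
        discordant=bool(calls["discordant"][0]),
        arbitrated=bool(calls["arbitrated"][0]),
        final_call=RECALL if recall else NORMAL,
        recall_result=recall_result,
        classification=classification,
    )


def next_invitation(current_age: float, attended: bool, policy: ScreeningPolicy) -> float | None:
    """Age of the next screening invitation, or ``None`` after the programme.

    Attendance does not alter the cadence: attenders and non-attenders alike
    are re-invited one interval later.  Invitations stop once the next slot
    would fall beyond the last-invitation age (end_age), so with the default
    triennial 50-70 policy the final invitation is at 68.
    """
    if current_age < policy.start_age:
        raise ValueError("no invitations before the programme start age")
    nxt = current_age + policy.interval
    return nxt if nxt <= policy.end_age else None


def invitation_ages(policy: ScreeningPolicy) -> list[float]:
    """All invitation ages under the policy (50, 53, ..., 68 by default)."""
    ages = [policy.start_age]
    while (nxt := next_invitation(ages[-1], True, policy)) is not None:
        ages.append(nxt)
    return ages
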