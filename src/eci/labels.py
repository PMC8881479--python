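"""States of consciousness and their arousal/awareness labels.

Every recording state (sleep stage, anesthetic, clinical diagnosis) maps to a
fixed pair of binary component labels: arousal (wakefulness) and awareness
(subjective experience).  The two components dissociate — REM sleep and
ketamine anesthesia are low-arousal yet high-awareness, and unresponsive
wakefulness syndrome (UWS) is high-arousal yet low-awareness — which is
exactly what the two independently trained classifiers exploit.
"""

from __future__ import annotations

from dataclasses import dataclass

LOW = "low"
HIGH = "high"

#: state code -> (arousal, awareness)
STATE_LABELS: dict[str, tuple[str, str]] = {
    "wake": (HIGH, HIGH),       # healthy wakefulness
    "rem": (LOW, HIGH),         # REM sleep with dream reports
    "nrem": (LOW, LOW),         # NREM (stage 3) sleep, no reports
    "ketamine": (LOW, HIGH),    # dissociative anesthesia, vivid dreams
    "propofol": (LOW, LOW),
    "xenon": (LOW, LOW),
    "wake_pre": (HIGH, HIGH),   # wakefulness recorded before anesthesia
    "mcs": (HIGH, HIGH),        # minimally conscious state
    "mcs_star": (HIGH, HIGH),   # non-behavioral MCS (neuroimaging diagnosis)
    "uws": (HIGH, LOW),         # unresponsive wakefulness syndrome
}

#: state code -> recording domain (clinical condition of acquisition)
STATE_DOMAINS: dict[str, str] = {
    "wake": "sleep",
    "rem": "sleep",
    "nrem": "sleep",
    "ketamine": "anesthesia",
    "propofol": "anesthesia",
    "xenon": "anesthesia",
    "wake_pre": "anesthesia",
    "mcs": "doc",
    "mcs_star": "doc",
    "uws": "doc",
}

DOMAINS = ("sleep", "anesthesia", "doc")
COMPONENTS = ("arousal", "awareness")


@dataclass(frozen=True)
class ConsciousnessLabel:
    """Binary arousal/awareness pair attached to a state code."""

    arousal: str
    awareness: str

    def __post_init__(self) -> None:
        for v in (self.arousal, self.awareness):
            if v not in (LOW, HIGH):
                raise ValueError(f"label must be 'low' or 'high', got {v!r}")

    def component(self, name: str) -> str:
        if name not in COMPONENTS:
            raise ValueError(f"unknown component {name!r}; expected one of {COMPONENTS}")
        return self.arousal if name == "arousal" else self.awareness


def label_for_state(state: str) -> ConsciousnessLabel:
    """Return the fixed (arousal, awareness) label of a state code."""
    try:
        aro, awa = STATE_LABELS[state]
    except KeyError:
        known = ", ".join(sorted(STATE_LABELS))
        raise ValueError(f"unknown state code {state!r}; known states: {known}") from None
    return ConsciousnessLabel(aro, awa)


def domain_for_state(state: str) -> str:
    """Return the recording domain (sleep / anesthesia / doc) of a state code."""
    if state not in STATE_DOMAINS:
        raise ValueError(f"unknown state code {state!r}")
    return STATE_DOMAINS[state]
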