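"""The 18 DSM ADHD symptom criteria in canonical order.

Nine inattentive criteria are followed by nine hyperactive/impulsive
criteria.  The short contractions used throughout the package follow the
usual abbreviations for the DSM wording (e.g. ``closeatt`` = "fails to give
close attention to details", ``interrupt`` = "interrupts or intrudes on
others").  Symptom identity is fixed by this order, not by any file layout.
"""

from __future__ import annotations

INATTENTIVE: tuple[str, ...] = (
    "closeatt",  # fails close attention / careless mistakes
    "susatt",    # difficulty sustaining attention
    "listen",    # does not seem to listen
    "instruct",  # does not follow through on instructions
    "org",       # difficulty organizing
    "avoid",     # avoids sustained mental effort
    "loses",     # loses things
    "distract",  # easily distracted
    "forget",    # forgetful
)

HYPERACTIVE: tuple[str, ...] = (
    "fidget",    # fidgets / squirms in seat
    "seat",      # leaves seat
    "runs",      # runs about or climbs excessively
    "quiet",     # difficulty playing quietly
    "motor",     # "driven by a motor"
    "talks",     # talks excessively
    "blurts",    # blurts out answers
    "turn",      # difficulty awaiting turn
    "interrupt", # interrupts or intrudes
)

SYMPTOMS: tuple[str, ...] = INATTENTIVE + HYPERACTIVE

N_SYMPTOMS = len(SYMPTOMS)
N_PER_DOMAIN = 9

#: domain tag per symptom, aligned with SYMPTOMS
DOMAINS: dict[str, str] = {
    **{s: "inattentive" for s in INATTENTIVE},
    **{s: "hyperactive" for s in HYPERACTIVE},
}

#: column indices of each domain within a canonical 18-vector
IA_SLICE = slice(0, 9)
HI_SLICE = slice(9, 18)
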