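"""Configural frequency analysis of diagnostic symptom patterns.

The DSM diagnostic rule (at least 6 of 9 symptoms in a domain) induces a
combinatorial space of qualifying on/off symptom configurations.  This module
counts that space in closed form with exact integer arithmetic, classifies
individual profiles into presentations (subtypes), and tabulates the observed
pattern census of a cohort — how many participants carry a symptom pattern
seen in no one else.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .symptoms import HI_SLICE, IA_SLICE, N_PER_DOMAIN

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import CohortTable

SUBTYPES = ("ADHD-I", "ADHD-H", "ADHD-CT")


@dataclass(frozen=True)
class DiagnosticRule:
    """Symptom-count diagnostic rule: ``threshold`` of ``n_*`` per domain."""

    n_inattentive: int = 9
    n_hyperactive: int = 9
    threshold: int = 6

    def __post_init__(self) -> None:
        # thresholds above the domain size are permitted and simply
        # unattainable (all configuration counts are 0)
        if self.threshold < 1:
            raise ValueError(f"threshold must be >= 1; got {self.threshold}")


DEFAULT_RULE = DiagnosticRule()


def binomial(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k); 0 outside 0 <= k <= n."""
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    if k < 0 or k > n:
        return 0
    return math.comb(n, k)


def classify_counts(ia: int, hi: int, rule: DiagnosticRule = DEFAULT_RULE) -> str:
    """Subtype label from per-domain symptom counts."""
    t = rule.threshold
    if ia >= t and hi < t:
        return "ADHD-I"
    if hi >= t and ia < t:
        return "ADHD-H"
    if ia >= t and hi >= t:
        return "ADHD-CT"
    return "none"


def classify_profile(profile: Sequence[int], rule: DiagnosticRule = DEFAULT_RULE) -> str:
    """Subtype label for an 18-item binary profile (canonical order)."""
    arr = np.asarray(profile)
    return classify_counts(int(arr[IA_SLICE].sum()), int(arr[HI_SLICE].sum()), rule)


def count_configurations_at(ia: int, hi: int, rule: DiagnosticRule = DEFAULT_RULE) -> int:
    """Number of distinct profiles with exactly ``ia`` inattentive and ``hi``
    hyperactive/impulsive symptoms: C(9, ia) * C(9, hi)."""
    if not (0 <= ia <= rule.n_inattentive and 0 <= hi <= rule.n_hyperactive):
        raise ValueError(f"counts out of range: ia={ia}, hi={hi}")
    return binomial(rule.n_inattentive, ia) * binomial(rule.n_hyperactive, hi)


def count_diagnostic_configurations(rule: DiagnosticRule = DEFAULT_RULE) -> dict[str, int]:
    """Closed-form census of qualifying symptom configurations per subtype.

    ADHD-I sums C(n_ia, k) for k at/above threshold times C(n_hi, j) for j
    below it; ADHD-H is symmetric; ADHD-CT takes both domains at/above
    threshold.  With the default 9+9 rule and threshold 6 this yields 49,660
    configurations for each single-presentation subtype, 16,900 for the
    combined type, and 116,220 in total.
    """
    t = rule.threshold
    ia_hi = sum(binomial(rule.n_inattentive, k) for k in range(t, rule.n_inattentive + 1))
    ia_lo = sum(binomial(rule.n_inattentive, k) for k in range(0, t))
    hi_hi = sum(binomial(rule.n_hyperactive, k) for k in range(t, rule.n_hyperactive + 1))
    hi_lo = sum(binomial(rule.n_hyperactive, k) for k in range(0, t))
    counts = {
        "ADHD-I": ia_hi * hi_lo,
        "ADHD-H": hi_hi * ia_lo,
        "ADHD-CT": ia_hi * hi_hi,
    }
    counts["total"] = sum(counts.values())
    return counts


def enumerate_diagnostic_configurations(rule: DiagnosticRule = DEFAULT_RULE) -> dict[str, int]:
    """Brute-force cross-check: classify all 2^18 profiles by domain counts.

    Enumerates (ia, hi) count pairs weighted by C(9, ia) * C(9, hi), which is
    equivalent to — and verified in tests against — walking all 262,144 bit
    patterns explicitly.
    """
    counts = dict.fromkeys(SUBTYPES, 0)
    for ia in range(rule.n_inattentive + 1):
        for hi in range(rule.n_hyperactive + 1):
            label = classify_counts(ia, hi, rule)
            if label != "none":
                counts[label] += count_configurations_at(ia, hi, rule)
    counts["total"] = sum(counts[s] for s in SUBTYPES)
    return counts


@dataclass
class ConfigurationCensus:
    """Observed symptom-pattern frequencies for one group of participants."""

    frequencies: Mapping[str, int]          # 18-bit pattern string -> count
    n: int                                  # cohort size censused
    n_unique: int                           # patterns carried by exactly one participant
    prop_unique: float                      # n_unique / n
    modal_patterns: tuple[str, ...]         # most frequent pattern(s), lexicographic
    modal_frequency: int
    theoretical: dict[str, int] = field(default_factory=count_diagnostic_configurations)


def pattern_census(
    cohort: "CohortTable | pd.DataFrame | np.ndarray",
    group: str | None = None,
    rule: DiagnosticRule = DEFAULT_RULE,
) -> ConfigurationCensus:
    """Census of observed 18-bit symptom patterns, optionally group-filtered.

    ``n_unique`` counts participants whose exact pattern occurs once in the
    filtered group; ties for the modal pattern are all reported, sorted.
    """
    profiles = _extract_profiles(cohort, group)
    if len(profiles) == 0:
        raise ValueError(f"empty census: no rows for group filter {group!r}")
    patterns = ["".join(str(int(v)) for v in row) for row in profiles]
    freq = Counter(patterns)
    n = len(patterns)
    n_unique = sum(1 for c in freq.values() if c == 1)
    modal_frequency = max(freq.values())
    modal = tuple(sorted(p for p, c in freq.items() if c == modal_frequency))
    return ConfigurationCensus(
        frequencies=dict(freq),
        n=n,
        n_unique=n_unique,
        prop_unique=n_unique / n,
        modal_patterns=modal,
        modal_frequency=modal_frequency,
        theoretical=count_diagnostic_configurations(rule),
    )


def domain_count_crosstab(cohort: "CohortTable") -> pd.DataFrame:
    """Per-subtype distribution of summed symptom counts in each domain.

    One row per (subtype, domain, count) with frequency and percentage of the
    subtype's participants; percentages sum to 100 within subtype x domain.
    """
    profiles = _extract_profiles(cohort, None)
    df = cohort.data
    ia_counts = profiles[:, IA_SLICE].sum(axis=1)
    hi_counts = profiles[:, HI_SLICE].sum(axis=1)
    rows = []
    groups = [("ADHD-I", None), ("ADHD-H", None), ("ADHD-CT", None), ("control", None)]
    for label, _ in groups:
        if label == "control":
            mask = (df["group"] == "control").to_numpy()
        else:
            mask = (df["subtype"] == label).to_numpy()
        n_sub = int(mask.sum())
        if n_sub == 0:
            continue
        for domain, counts in (("inattentive", ia_counts), ("hyperactive", hi_counts)):
            sub = counts[mask]
            for c in range(N_PER_DOMAIN + 1):
                freq = int((sub == c).sum())
                if freq:
                    rows.append(
                        {
                            "subtype": label,
                            "domain": domain,
                            "symptom_count": c,
                            "frequency": freq,
                            "percent": 100.0 * freq / n_sub,
                        }
                    )
    return pd.DataFrame(rows, columns=["subtype", "domain", "symptom_count", "frequency", "percent"])


def _extract_profiles(cohort, group: str | None) -> np.ndarray:
    from .data_io import CohortTable  # local import to avoid a cycle

    if isinstance(cohort, CohortTable):
        if group is not None:
            return cohort.profiles[(cohort.data["group"] == group).to_numpy()]
        return cohort.profiles
    arr = np.asarray(cohort if not isinstance(cohort, pd.DataFrame) else cohort.to_numpy())
    return arr
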