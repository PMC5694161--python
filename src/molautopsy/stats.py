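"""Cohort-level descriptive and inferential statistics.

Covers the demographics summary, the overlapping age groups (infants,
minors, full cohort), the 2x2 combined forensic/molecular diagnostic-yield
table, temporal death-distribution histograms, and an exact binomial test
for day-of-week clustering of deaths (e.g. seven of eight infant deaths on
two midweek days).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as _stats

from .io import CaseRecord

INFANT_MAX_MONTHS = 12.0  # infant: age strictly under one year
MINOR_MAX_MONTHS = 216.0  # <= 18 years

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


@dataclass(slots=True)
class YieldTable:
    """2x2 combined diagnostic yield: molecular (MA) x forensic (FA)."""

    n_pp: int  # MA+ FA+
    n_pn: int  # MA+ FA-
    n_np: int  # MA- FA+
    n_nn: int  # MA- FA-

    def __post_init__(self) -> None:
        if min(self.n_pp, self.n_pn, self.n_np, self.n_nn) < 0:
            raise ValueError("yield counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pn + self.n_np + self.n_nn

    @property
    def ma_positive(self) -> int:
        return self.n_pp + self.n_pn

    @property
    def fa_positive(self) -> int:
        return self.n_pp + self.n_np

    def as_dict(self) -> dict:
        n = self.n
        pct = lambda k: 100.0 * k / n if n else 0.0
        return {
            "n": n,
            "ma_pos_fa_pos": self.n_pp,
            "ma_pos_fa_neg": self.n_pn,
            "ma_neg_fa_pos": self.n_np,
            "ma_neg_fa_neg": self.n_nn,
            "ma_positive": self.ma_positive,
            "fa_positive": self.fa_positive,
            "pct_ma_pos_fa_pos": pct(self.n_pp),
            "pct_ma_neg_fa_neg": pct(self.n_nn),
            "pct_ma_positive": pct(self.ma_positive),
            "pct_fa_positive": pct(self.fa_positive),
        }


@dataclass(slots=True)
class TemporalTest:
    """Exact binomial upper-tail test for clustering on d of 7 weekdays."""

    n: int
    k: int
    d: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if not 1 <= self.d <= 7:
            raise ValueError(f"need 1 <= d <= 7, got d={self.d}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def included_cases(cases: list[CaseRecord]) -> list[CaseRecord]:
    return [c for c in cases if c.include_in_cohort]


def age_groups(cases: list[CaseRecord]) -> dict[str, list[CaseRecord]]:
    """Overlapping age groups: infants (< 12 months), minors (<= 18 years),
    full cohort.  The sibling-pair case is grouped by its youngest proband.
    """
    cohort = included_cases(cases)
    return {
        "infants": [c for c in cohort if c.youngest_age_months < INFANT_MAX_MONTHS],
        "minors": [c for c in cohort if c.youngest_age_months <= MINOR_MAX_MONTHS],
        "full": list(cohort),
    }


def yield_table(cases: list[CaseRecord]) -> YieldTable:
    """Cross-tabulate molecular vs forensic autopsy status.

    Every included case must carry both statuses; a missing one is fatal
    (compute MA status first via the filter cascade if absent).
    """
    counts = {"pp": 0, "pn": 0, "np": 0, "nn": 0}
    for c in included_cases(cases):
        if c.ma_status is None:
            raise ValueError(f"case {c.case_id} has no molecular-autopsy status")
        key = ("p" if c.ma_status == "positive" else "n") + ("p" if c.fa_status == "positive" else "n")
        counts[key] += 1
    return YieldTable(n_pp=counts["pp"], n_pn=counts["pn"], n_np=counts["np"], n_nn=counts["nn"])


def temporal_histograms(
    cases: list[CaseRecord],
    window: tuple[int, int] = (8, 20),
) -> dict:
    """Death-time histograms by weekday, hour and month.

    Cases without a timestamp land in the ``unknown`` bin of each
    histogram.  ``window_fraction`` is the share of timestamped deaths in
    the clock window [start, end) — inclusive start, exclusive end; the
    default 08:00-20:00 covers the daytime 12-hour window.
    """
    by_weekday = dict.fromkeys(WEEKDAYS, 0)
    by_hour = {h: 0 for h in range(24)}
    by_month = dict.fromkeys(MONTHS, 0)
    unknown = 0
    in_window = 0
    timestamped = 0
    start, end = window
    for c in included_cases(cases):
        if c.death_time is None:
            unknown += 1
            continue
        timestamped += 1
        t = c.death_time
        by_weekday[WEEKDAYS[t.weekday()]] += 1
        by_hour[t.hour] += 1
        by_month[MONTHS[t.month - 1]] += 1
        if start <= t.hour < end:
            in_window += 1
    return {
        "by_weekday": by_weekday,
        "by_hour": by_hour,
        "by_month": by_month,
        "unknown": unknown,
        "window": {"start_hour": start, "end_hour": end},
        "window_fraction": in_window / timestamped if timestamped else None,
    }


def binomial_day_cluster_test(k: int, n: int, d: int = 2) -> TemporalTest:
    """Exact upper-tail probability of >= k of n deaths on d of 7 days.

    Under uniform weekdays each death lands on the designated d-day set
    with probability d/7; the p-value is sum_{i=k}^{n} C(n,i) (d/7)^i
    (1-d/7)^(n-i).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 1 <= d <= 7:
        raise ValueError(f"need 1 <= d <= 7, got d={d}")
    p = float(_stats.binom.sf(k - 1, n, d / 7.0))
    return TemporalTest(n=n, k=k, d=d, p_value=min(p, 1.0))


def weekday_cluster_test(cases: list[CaseRecord], days: tuple[int, ...] = (2, 3)) -> TemporalTest:
    """Day-cluster test on timestamped cases; ``days`` are ISO weekday
    indices 0=Mon..6=Sun (default Wednesday+Thursday)."""
    stamped = [c for c in included_cases(cases) if c.death_time is not None]
    if not stamped:
        raise ValueError("no timestamped cases")
    k = sum(1 for c in stamped if c.death_time.weekday() in days)
    return binomial_day_cluster_test(k=k, n=len(stamped), d=len(days))


def demographics(cases: list[CaseRecord], site_filter: str | None = None) -> dict:
    """Sex, race and site counts, optionally restricted by a case-id regex.

    Race labels are reported verbatim (including 'NA' and 'Biracial'); no
    percentage convention is imposed.
    """
    import re

    cohort = included_cases(cases)
    if site_filter is not None:
        pattern = re.compile(site_filter)
        cohort = [c for c in cohort if pattern.match(c.case_id)]
    sex_counts = {"female": 0, "male": 0}
    race_counts: dict[str, int] = {}
    site_counts: dict[str, int] = {}
    for c in cohort:
        sex_counts[c.sex] += 1
        race_counts[c.race or "NA"] = race_counts.get(c.race or "NA", 0) + 1
        site_counts[c.site_label] = site_counts.get(c.site_label, 0) + 1
    return {
        "n": len(cohort),
        "sex": sex_counts,
        "race": dict(sorted(race_counts.items())),
        "site": dict(sorted(site_counts.items())),
    }


def cohort_report(cases: list[CaseRecord]) -> dict:
    """All cohort-level tables in one machine-readable structure."""
    groups = age_groups(cases)
    report = {
        "n_cases": len(included_cases(cases)),
        "age_groups": {k: len(v) for k, v in groups.items()},
        "demographics": demographics(cases),
        "yield": yield_table(cases).as_dict(),
    }
    if any(c.death_time is not None for c in included_cases(cases)):
        report["temporal"] = temporal_histograms(cases)
    return report
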