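"""Synthetic stratified patient cohorts with planted comorbidity structure.

The generator emulates hospital discharge records: each case belongs to one
age x sex x SES stratum and carries a small set of ICD-10 diagnosis codes.
Within a stratum, disease indicators are independent Bernoulli draws with
configurable marginal prevalences, except for explicitly *planted* pairs
(A, B, rho): their joint distribution is the 2x2 table with

    P(A and B) = rho * p_A * p_B

and the configured margins preserved, so rho = 1 is independence and
rho > 1 is a known, exactly quantified co-occurrence enrichment. Planted
pairs are the ground truth against which edge recovery is measured.

Records drawing more codes than the per-record cap (default 6, one
principal diagnosis plus five comorbidities) lose the excess uniformly at
random — never preferentially planted codes — and the truncation rate is
reported, with a warning above 1% because capping attenuates planted
enrichment. Records drawing zero codes are emitted with an empty code set
(counted in the report); the ingest step excludes them, as it would real
cases with no usable diagnosis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .records import SES_LEVELS, SEXES, PatientRecord, StratumSpec

__all__ = [
    "ConfigError",
    "TruncationWarning",
    "PlantedPair",
    "SyntheticConfig",
    "CohortReport",
    "generate_cohort",
    "ground_truth_edges",
]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration; the message names the field."""


class TruncationWarning(UserWarning):
    """More than 1% of generated records lost codes to the per-record cap."""


@dataclass(frozen=True)
class PlantedPair:
    """A pairwise co-occurrence enrichment planted in one stratum."""

    code_a: str
    code_b: str
    stratum: str
    rho: float

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.code_a, self.code_b)))


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort.

    Parameters
    ----------
    code_universe : sequence of str
        ICD-10 codes that can occur.
    strata : sequence of StratumSpec
        Strata to populate, each with ``n_per_stratum`` cases.
    n_per_stratum : int
        Cases generated per stratum.
    prevalence : mapping stratum label -> (mapping code -> prob | float)
        Per-stratum marginal prevalence for each code; a bare float applies
        to every code in the universe; missing codes default to 0.
    planted_pairs : sequence of PlantedPair
        Enrichments; rho >= 1, rho * p_A * p_B <= min(p_A, p_B), and within
        a stratum no two planted pairs may share a code (keeps the planted
        joint tables exact without copula machinery).
    max_codes_per_record : int
        Cap on codes per case, default 6.
    seed : int
        RNG seed; the whole cohort is a deterministic function of it.
    """

    code_universe: Sequence[str]
    strata: Sequence[StratumSpec]
    n_per_stratum: int
    prevalence: Mapping[str, Union[Mapping[str, float], float]]
    planted_pairs: Sequence[PlantedPair] = field(default_factory=tuple)
    max_codes_per_record: int = 6
    seed: int = 0

    def validate(self) -> None:
        if not self.code_universe:
            raise ConfigError("code_universe: must be non-empty")
        if len(set(self.code_universe)) != len(self.code_universe):
            raise ConfigError("code_universe: duplicate codes")
        if not self.strata:
            raise ConfigError("strata: must be non-empty")
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise ConfigError("strata: duplicate labels")
        for s in self.strata:
            if s.sex not in SEXES or s.ses not in SES_LEVELS:
                raise ConfigError(f"strata: {s.label!r} has unknown sex/ses")
        if int(self.n_per_stratum) < 1:
            raise ConfigError("n_per_stratum: must be >= 1")
        if int(self.max_codes_per_record) < 1:
            raise ConfigError("max_codes_per_record: must be >= 1")
        universe = set(self.code_universe)
        for label, prev in self.prevalence.items():
            if label not in labels:
                raise ConfigError(f"prevalence: unknown stratum {label!r}")
            if isinstance(prev, Mapping):
                bad = set(prev) - universe
                if bad:
                    raise ConfigError(f"prevalence[{label!r}]: codes {sorted(bad)} not in universe")
                vals = prev.values()
            else:
                vals = [float(prev)]
            for p in vals:
                if not 0.0 <= float(p) <= 1.0:
                    raise ConfigError(f"prevalence[{label!r}]: value {p} outside [0, 1]")
        seen: dict[str, set[str]] = {}
        for pp in self.planted_pairs:
            if pp.code_a == pp.code_b:
                raise ConfigError(f"planted_pairs: self-pair {pp.code_a!r}")
            if pp.code_a not in universe or pp.code_b not in universe:
                raise ConfigError(f"planted_pairs: {pp.pair} not in code_universe")
            if pp.stratum not in labels:
                raise ConfigError(f"planted_pairs: unknown stratum {pp.stratum!r}")
            if pp.rho < 1.0:
                raise ConfigError(f"planted_pairs: rho={pp.rho} < 1 for {pp.pair}")
            pa = self.prevalence_of(pp.stratum, pp.code_a)
            pb = self.prevalence_of(pp.stratum, pp.code_b)
            p11 = pp.rho * pa * pb
            if p11 > min(pa, pb) + 1e-12:
                raise ConfigError(
                    f"planted_pairs: rho*p_A*p_B={p11:.4g} exceeds min marginal for {pp.pair}"
                )
            if pa + pb - p11 > 1.0 + 1e-12:
                raise ConfigError(
                    f"planted_pairs: joint table for {pp.pair} has negative P(neither)"
                )
            used = seen.setdefault(pp.stratum, set())
            if used & {pp.code_a, pp.code_b}:
                raise ConfigError(
                    f"planted_pairs: overlapping planted pairs share a code in {pp.stratum!r}"
                )
            used |= {pp.code_a, pp.code_b}

    def prevalence_of(self, stratum_label: str, code: str) -> float:
        prev = self.prevalence.get(stratum_label, {})
        if isinstance(prev, Mapping):
            return float(prev.get(code, 0.0))
        return float(prev)

    def prevalence_vector(self, stratum_label: str) -> np.ndarray:
        return np.array(
            [self.prevalence_of(stratum_label, c) for c in self.code_universe]
        )


@dataclass
class CohortReport:
    """Generation accounting: cohort size, cap truncations and empty draws."""

    n_records: int
    n_truncated: int
    codes_removed: int
    n_empty: int

    @property
    def truncation_rate(self) -> float:
        return self.n_truncated / self.n_records if self.n_records else 0.0


def generate_cohort(
    config: SyntheticConfig, with_report: bool = False
) -> list[PatientRecord] | tuple[list[PatientRecord], CohortReport]:
    """Generate the synthetic cohort described by ``config``.

    Deterministic given ``config.seed``. Ages are drawn uniformly within the
    stratum bracket (open-ended brackets use a 20-year span); sex and SES
    come directly from the stratum.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = list(config.code_universe)
    cap = int(config.max_codes_per_record)

    records: list[PatientRecord] = []
    n_truncated = 0
    codes_removed = 0
    n_empty = 0
    for stratum in config.strata:
        n = int(config.n_per_stratum)
        p = config.prevalence_vector(stratum.label)
        occ = rng.random((n, len(universe))) < p
        for pp in config.planted_pairs:
            if pp.stratum != stratum.label:
                continue
            ia = universe.index(pp.code_a)
            ib = universe.index(pp.code_b)
            pa, pb = p[ia], p[ib]
            p11 = pp.rho * pa * pb
            # joint 2x2 table with P(both)=rho*pa*pb and preserved margins
            u = rng.random(n)
            occ[:, ia] = u < pa  # P(both) + P(A only) = pa
            occ[:, ib] = (u < p11) | ((u >= pa) & (u < pa + pb - p11))
        age_hi = stratum.age_hi if stratum.age_hi is not None else stratum.age_lo + 19
        ages = rng.integers(stratum.age_lo, age_hi + 1, size=n)
        for i in range(n):
            idxs = np.flatnonzero(occ[i])
            if len(idxs) > cap:
                keep = rng.choice(idxs, size=cap, replace=False)
                codes_removed += len(idxs) - cap
                n_truncated += 1
                idxs = np.sort(keep)
            codes = frozenset(universe[j] for j in idxs)
            if not codes:
                n_empty += 1
            records.append(
                PatientRecord(
                    case_id=f"{stratum.label}-{i:06d}",
                    age=int(ages[i]),
                    sex=stratum.sex,
                    ses=stratum.ses,
                    codes=codes,
                )
            )
    report = CohortReport(
        n_records=len(records),
        n_truncated=n_truncated,
        codes_removed=codes_removed,
        n_empty=n_empty,
    )
    if report.truncation_rate > 0.01:
        warnings.warn(
            f"{report.truncation_rate:.2%} of records exceeded the "
            f"{cap}-code cap and were truncated; planted enrichments may be attenuated",
            TruncationWarning,
            stacklevel=2,
        )
    return (records, report) if with_report else records


def ground_truth_edges(
    config: SyntheticConfig, stratum: StratumSpec | str
) -> set[tuple[str, str]]:
    """Planted pairs with rho > 1 for one stratum (rho = 1 is independence).

    Raises ``KeyError`` for a stratum not in the config.
    """
    label = stratum.label if isinstance(stratum, StratumSpec) else str(stratum)
    if label not in {s.label for s in config.strata}:
        raise KeyError(f"unknown stratum {label!r}")
    return {pp.pair for pp in config.planted_pairs if pp.stratum == label and pp.rho > 1.0}
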