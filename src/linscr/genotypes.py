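"""Non-invasive microsatellite genotyping: replicates to individuals.

Implements the consensus-calling, sex-assignment, identity (PIsibs),
sample-matching and error-rate conventions used for fecal-DNA
capture-recapture surveys:

* a heterozygote allele must be seen in >= 2 independent PCR replicates,
  a homozygote in >= 3 with no other allele ever observed;
* Y-marker amplification in >= 2 replicates confirms a male, exactly one
  replicate gives an unconfirmed male, and zero replicates with >= 8
  autosomal loci typed gives a female;
* samples match into an individual when their genotypes agree at >= 8
  shared typed loci, with remaining mismatches explainable by allelic
  dropout (conservative rule) or with no mismatches at all (lenient rule);
* per-amplification allelic-dropout and false-allele rates are estimated
  from the first two replicates of samples with full consensus genotypes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .history import DetectionHistory
from .network import DetectorArray

__all__ = [
    "ReplicateCalls",
    "ConsensusGenotype",
    "IndividualAssignment",
    "ErrorRates",
    "call_consensus",
    "assign_sex",
    "pi_sibs",
    "meets_pi_sibs",
    "match_genotypes",
    "error_rates",
    "build_detection_history",
    "randomized_subsample",
]

FEMALE_MIN_LOCI = 8
MATCH_MIN_LOCI = 8
PI_SIBS_CUTOFF = 0.01


@dataclass
class ReplicateCalls:
    """Replicate PCR observations for one sample.

    ``calls`` maps locus -> list of replicates; each replicate is a tuple of
    0, 1 or 2 allele labels (empty tuple = failed amplification).
    """

    sample_id: str
    latrine_id: str
    occasion: int
    calls: dict[str, list[tuple[str, ...]]]
    y_positives: int = 0
    y_attempts: int = 0

    def __post_init__(self) -> None:
        if self.y_positives < 0 or self.y_attempts < 0:
            raise ValueError("Y-marker counts must be nonnegative")
        if self.y_positives > self.y_attempts:
            raise ValueError("Y positives cannot exceed attempts")


@dataclass
class ConsensusGenotype:
    """Per-sample consensus: unordered allele pair (or None) per locus."""

    sample_id: str
    genotype: dict[str, tuple[str, str] | None]
    sex: str = "unknown"  # female | confirmed_male | unconfirmed_male | unknown
    latrine_id: str | None = None
    occasion: int | None = None

    @property
    def n_typed(self) -> int:
        return sum(1 for g in self.genotype.values() if g is not None)

    def typed_loci(self) -> set[str]:
        return {l for l, g in self.genotype.items() if g is not None}


@dataclass
class ErrorRates:
    """Per-amplification genotyping error rates with underlying counts."""

    dropout_rate: float | None
    false_allele_rate: float | None
    n_dropout_events: int = 0
    n_het_amplifications: int = 0
    n_false_allele_events: int = 0
    n_amplifications: int = 0


@dataclass
class IndividualAssignment:
    """Sample -> individual mapping with consolidated genotypes and sexes."""

    rule: str
    sample_to_individual: dict[str, str]
    genotypes: dict[str, dict[str, tuple[str, str] | None]]
    sexes: dict[str, str]                       # individual -> female|male|unconfirmed_male|unknown
    detections: dict[str, list[tuple[str, int]]]  # individual -> [(latrine, occasion)]
    excluded_samples: list[str] = field(default_factory=list)
    flagged_individuals: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def n_detections(self) -> int:
        return sum(len(v) for v in self.detections.values())


def _consensus_locus(replicates: list[tuple[str, ...]]) -> tuple[str, str] | None:
    attempted = [r for r in replicates]
    if len(attempted) < 2:
        return None
    seen: dict[str, int] = {}
    for rep in attempted:
        for a in set(rep):
            seen[a] = seen.get(a, 0) + 1
    confirmed = sorted(a for a, c in seen.items() if c >= 2)
    if len(confirmed) == 2:
        return (confirmed[0], confirmed[1])
    if len(seen) == 1:  # only one allele ever observed
        (allele, count), = seen.items()
        if count >= 3:
            return (allele, allele)
    return None


def call_consensus(rep: ReplicateCalls) -> ConsensusGenotype:
    """Consensus genotype from replicate PCRs.

    A locus is called heterozygous A/B when exactly two alleles were each
    observed in >= 2 replicates; homozygous A/A when A is the only allele
    ever observed and it appeared in >= 3 replicates; otherwise missing
    (including ambiguous cases with three confirmed alleles).
    """
    genotype = {locus: _consensus_locus(reps) for locus, reps in rep.calls.items()}
    cg = ConsensusGenotype(
        sample_id=rep.sample_id,
        genotype=genotype,
        latrine_id=rep.latrine_id,
        occasion=rep.occasion,
    )
    cg.sex = assign_sex(rep.y_positives, rep.y_attempts, cg.n_typed)
    return cg


def assign_sex(y_positives: int, y_attempts: int, loci_typed: int) -> str:
    """Sex class from Y-marker replicates.

    The Y marker amplifies in males only, so a negative can be a female or
    a male with dropout; >= 8 typed autosomal loci indicate enough DNA to
    rule out dropout across the attempted replicates.
    """
    if y_positives < 0 or y_attempts < 0 or loci_typed < 0:
        raise ValueError("counts must be nonnegative")
    if y_attempts and not 3 <= y_attempts <= 6:
        warnings.warn(f"{y_attempts} Y-marker replicates outside the usual 3-6")
    if y_positives >= 2:
        return "confirmed_male"
    if y_positives == 1:
        return "unconfirmed_male"
    if loci_typed >= FEMALE_MIN_LOCI:
        return "female"
    return "unknown"


def pi_sibs(allele_freqs: dict[str, np.ndarray] | list, loci: list[str] | None = None) -> float:
    """Multi-locus probability of identity among full siblings.

    Per locus ``0.25 + 0.5*S2 + 0.5*S2^2 - 0.25*S4`` with S2 = sum(p^2),
    S4 = sum(p^4); multiplied over loci (log-space accumulation).
    """
    if isinstance(allele_freqs, dict):
        keys = loci if loci is not None else list(allele_freqs)
        freq_list = [np.asarray(allele_freqs[k], float) for k in keys]
    else:
        freq_list = [np.asarray(f, float) for f in allele_freqs]
    log_total = 0.0
    for p in freq_list:
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("allele frequencies must be in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")
        s2 = float(np.sum(p**2))
        s4 = float(np.sum(p**4))
        log_total += np.log(0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4)
    return float(np.exp(log_total))


def meets_pi_sibs(
    consensus: ConsensusGenotype,
    allele_freqs: dict[str, np.ndarray],
    cutoff: float = PI_SIBS_CUTOFF,
) -> bool:
    """Whether a sample's typed loci discriminate individuals well enough.

    Evaluates the sibling probability of identity over exactly the loci the
    sample was typed at.  Callers choose whether to exclude marginal samples
    (typed at few loci whose combined PIsibs exceeds the cutoff) or keep
    them; both policies are defensible and the choice is left explicit.
    """
    loci = sorted(consensus.typed_loci())
    if not loci:
        return False
    return pi_sibs(allele_freqs, loci=loci) <= cutoff


def _dropout_consistent(g1: tuple[str, str], g2: tuple[str, str]) -> bool:
    """One genotype heterozygous, the other homozygous for one of its alleles."""
    h1, h2 = g1[0] == g1[1], g2[0] == g2[1]
    if h1 == h2:
        return False
    homo, het = (g1, g2) if h1 else (g2, g1)
    return homo[0] in het


def _pair_matches(a: ConsensusGenotype, b: ConsensusGenotype, rule: str) -> bool:
    shared = a.typed_loci() & b.typed_loci()
    if len(shared) < MATCH_MIN_LOCI:
        return False
    mismatches = [l for l in shared if a.genotype[l] != b.genotype[l]]
    if len(shared) - len(mismatches) < MATCH_MIN_LOCI:
        return False
    if rule == "lenient":
        return len(mismatches) == 0
    return all(_dropout_consistent(a.genotype[l], b.genotype[l]) for l in mismatches)


def _consolidate(members: list[ConsensusGenotype]) -> tuple[dict, bool]:
    """Merge member genotypes; heterozygous calls override dropout homozygotes.

    Returns the consolidated genotype and a flag raised when transitive
    closure has chained together two members whose genotypes disagree
    non-dropout-consistently at >= 2 loci (an ambiguous chain).
    """
    flagged = False
    for a, b in itertools.combinations(members, 2):
        shared = a.typed_loci() & b.typed_loci()
        hard = sum(
            1 for l in shared
            if a.genotype[l] != b.genotype[l]
            and not _dropout_consistent(a.genotype[l], b.genotype[l])
        )
        if hard >= 2:
            flagged = True
            break
    loci = sorted({l for m in members for l in m.genotype})
    out: dict[str, tuple[str, str] | None] = {}
    conflicts = 0
    for locus in loci:
        calls = [m.genotype[locus] for m in members
                 if m.genotype.get(locus) is not None]
        if not calls:
            out[locus] = None
            continue
        distinct = sorted(set(calls))
        if len(distinct) == 1:
            out[locus] = distinct[0]
            continue
        hets = [g for g in distinct if g[0] != g[1]]
        if len(hets) == 1 and all(
            _dropout_consistent(g, hets[0]) for g in distinct if g != hets[0]
        ):
            out[locus] = hets[0]
        else:
            conflicts += 1
            out[locus] = distinct[0]  # arbitrary but deterministic
    return out, flagged or conflicts >= 2


def _individual_sex(members: list[ConsensusGenotype]) -> str:
    classes = {m.sex for m in members}
    if "confirmed_male" in classes:
        return "male"
    if "unconfirmed_male" in classes:
        # a female call alongside an unconfirmed male resolves to male
        return "male" if "female" in classes else "unconfirmed_male"
    if "female" in classes:
        return "female"
    return "unknown"


def match_genotypes(
    consensus: list[ConsensusGenotype],
    rule: str = "conservative",
    min_loci: int = MATCH_MIN_LOCI,
) -> IndividualAssignment:
    """Group samples into individuals by multilocus genotype matching.

    Conservative rule: samples merge when identical at >= ``min_loci`` shared
    typed loci and every remaining mismatch is dropout-consistent.  Lenient
    rule: any mismatch keeps samples apart.  Matching is closed transitively
    (union of pairwise matches); individuals whose members end up with
    irreconcilable genotypes at two or more loci are flagged, not unmerged.
    """
    if rule not in ("conservative", "lenient"):
        raise ValueError(f"unknown matching rule {rule!r}")
    usable = [c for c in consensus if c.n_typed >= min_loci]
    excluded = [c.sample_id for c in consensus if c.n_typed < min_loci]

    parent = list(range(len(usable)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(usable)), 2):
        if _pair_matches(usable[i], usable[j], rule):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[ConsensusGenotype]] = {}
    for i, c in enumerate(usable):
        clusters.setdefault(find(i), []).append(c)

    sample_to_individual: dict[str, str] = {}
    genotypes, sexes, detections = {}, {}, {}
    flagged = []
    for n, root in enumerate(sorted(clusters)):
        members = clusters[root]
        ind = f"I{n:03d}"
        geno, conflict = _consolidate(members)
        if conflict:
            flagged.append(ind)
        genotypes[ind] = geno
        sexes[ind] = _individual_sex(members)
        detections[ind] = [
            (m.latrine_id, m.occasion)
            for m in members
            if m.latrine_id is not None and m.occasion is not None
        ]
        for m in members:
            sample_to_individual[m.sample_id] = ind
    return IndividualAssignment(
        rule=rule,
        sample_to_individual=sample_to_individual,
        genotypes=genotypes,
        sexes=sexes,
        detections=detections,
        excluded_samples=excluded,
        flagged_individuals=flagged,
    )


def error_rates(
    replicates: list[ReplicateCalls],
    consensus: list[ConsensusGenotype],
    min_loci: int = 8,
    n_replicates_used: int = 2,
) -> ErrorRates:
    """Allelic-dropout and false-allele rates from early PCR replicates.

    Only samples with >= ``min_loci`` consensus loci contribute, and only
    their first ``n_replicates_used`` replicates per locus.  Dropout: an
    amplified replicate at a heterozygous consensus locus showing a single
    distinct allele, per heterozygous amplification.  False allele: an
    amplified replicate containing an allele absent from the consensus pair,
    per amplification.  Undefined (None) when a denominator is zero.
    """
    by_id = {c.sample_id: c for c in consensus if c.n_typed >= min_loci}
    het_amps = dropouts = amps = false_events = 0
    for rep in replicates:
        cg = by_id.get(rep.sample_id)
        if cg is None:
            continue
        for locus, reps in rep.calls.items():
            pair = cg.genotype.get(locus)
            if pair is None:
                continue
            for r in reps[:n_replicates_used]:
                alleles = set(r)
                if not alleles:
                    continue
                amps += 1
                if any(a not in pair for a in alleles):
                    false_events += 1
                if pair[0] != pair[1]:
                    het_amps += 1
                    if len(alleles) == 1:
                        dropouts += 1
    return ErrorRates(
        dropout_rate=dropouts / het_amps if het_amps else None,
        false_allele_rate=false_events / amps if amps else None,
        n_dropout_events=dropouts,
        n_het_amplifications=het_amps,
        n_false_allele_events=false_events,
        n_amplifications=amps,
    )


def build_detection_history(
    assignment: IndividualAssignment,
    detectors: DetectorArray,
    n_occasions: int,
    resolve_unconfirmed_male: bool = True,
) -> DetectionHistory:
    """Tabulate assigned samples into individual x detector x occasion counts.

    Counts keep with-replacement semantics: several samples of one individual
    at the same latrine and occasion all count.  By default unconfirmed males
    are coded male for the detection history.
    """
    ids = sorted(assignment.genotypes)
    counts = np.zeros((len(ids), detectors.n_detectors, n_occasions), int)
    for i, ind in enumerate(ids):
        for latrine, occ in assignment.detections[ind]:
            if latrine not in detectors.ids:
                raise KeyError(f"sample references unknown latrine {latrine!r}")
            if not 0 <= occ < n_occasions:
                raise KeyError(f"occasion {occ} outside 0..{n_occasions - 1}")
            counts[i, detectors.index_of(latrine), occ] += 1
    sex_map = {"female": "female", "confirmed_male": "male", "unknown": "unknown"}
    sex_map["male"] = "male"
    sex_map["unconfirmed_male"] = "male" if resolve_unconfirmed_male else "unknown"
    sexes = [sex_map[assignment.sexes[i]] for i in ids]
    return DetectionHistory(counts=counts, sexes=sexes, individual_ids=ids)


def randomized_subsample(
    samples: pd.DataFrame,
    seed: int,
    n_min: int = 3,
    n_max: int = 4,
) -> tuple[list[str], dict[str, str]]:
    """Seeded subsampling of field samples for genotyping.

    ``samples`` needs columns ``sample_id, scat_id, latrine_id, occasion``
    with up to two samples (duplicates) per scat.  One sample per scat goes
    into the candidate pool; within each latrine x occasion group, 3-4
    candidates are drawn at random.  Returns the selected primary sample ids
    and a primary -> duplicate fallback map (used when a primary fails
    genotyping).  With few enough samples this is a no-op selection.
    """
    rng = np.random.default_rng(seed)
    primaries = samples.sort_values("sample_id").groupby("scat_id", sort=True).head(1)
    fallback: dict[str, str] = {}
    for scat, grp in samples.groupby("scat_id", sort=True):
        s = grp.sort_values("sample_id")["sample_id"].tolist()
        if len(s) > 1:
            fallback[s[0]] = s[1]
    selected: list[str] = []
    for _, grp in primaries.groupby(["latrine_id", "occasion"], sort=True):
        k = int(rng.integers(n_min, n_max + 1))
        pool = grp["sample_id"].tolist()
        if len(pool) <= k:
            selected.extend(pool)
        else:
            selected.extend(sorted(rng.choice(pool, size=k, replace=False)))
    return sorted(selected), fallback
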