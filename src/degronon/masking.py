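"""Degron masking analysis: mapping partner binding sites and short linear
motifs onto tripartite degrons.

A *degron* is a degradation-targeting element of a substrate protein.  The
tripartite model distinguishes a primary degron (the E3-ligase-recruiting
sequence motif), a secondary degron (the ubiquitination site, "Ubsite") and a
tertiary degron (an intrinsically disordered region that engages the
proteasome).  A partner *masks* a degron when its experimentally mapped
binding region overlaps the degron, or lies within a small sequence window of
it ("adjacent").

Coordinates are 1-based and inclusive throughout (UniProt convention).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

#: Sequence window (in residues) within which a disjoint binding site still
#: counts as adjacent to a degron.
DEFAULT_ADJACENCY_WINDOW = 10

#: Minimum interaction confidence score retained for masking analysis.
DEFAULT_MIN_CONFIDENCE = 0.3


class DegronClass(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"


class FeatureKind(str, Enum):
    SUFFICIENT_BINDING_REGION = "sufficient_binding_region"
    BINDING_ASSOCIATED_REGION = "binding_associated_region"
    NECESSARY_BINDING_REGION = "necessary_binding_region"
    MUTATION_EVIDENCE = "mutation_evidence"


class MotifCategory(str, Enum):
    MODIFICATION = "modification"
    DOCKING = "docking"
    LIGAND_BINDING = "ligand_binding"
    TARGETING = "targeting"
    CLEAVAGE = "cleavage"


class Relation(str, Enum):
    OVERLAP = "overlap"
    ADJACENT = "adjacent"
    NONE = "none"


class Provenance(str, Enum):
    EXPERIMENTAL = "experimental"
    INFERRED = "inferred"


@dataclass(frozen=True)
class SequenceRegion:
    """A contiguous residue range on a protein, 1-based inclusive."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region on {self.protein_id}: "
                f"require 1 <= start <= end, got ({self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DegronAnnotation:
    """One tripartite degron element on a substrate."""

    region: SequenceRegion
    degron_class: DegronClass
    sequence: Optional[str] = None
    ubsite_position: Optional[int] = None
    provenance: Provenance = Provenance.EXPERIMENTAL

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != len(self.region):
            raise ValueError(
                f"degron sequence length {len(self.sequence)} does not match "
                f"region span {len(self.region)} on {self.region.protein_id}"
            )
        if (
            self.degron_class is DegronClass.SECONDARY
            and self.ubsite_position is not None
            and not (self.region.start <= self.ubsite_position <= self.region.end)
        ):
            raise ValueError("secondary degron Ubsite must lie within its region")


@dataclass(frozen=True)
class BindingFeature:
    """A partner's experimentally mapped binding region on a substrate."""

    substrate_id: str
    partner_id: str
    region: SequenceRegion
    feature_kind: FeatureKind
    confidence: float
    interaction_id: str = ""


@dataclass(frozen=True)
class MotifAnnotation:
    """An ELM-style short linear motif with a functional category."""

    region: SequenceRegion
    category: MotifCategory
    motif_id: str


@dataclass(frozen=True)
class MaskingResult:
    substrate_id: str
    partner_id: str
    degron: DegronAnnotation
    relation: Relation
    overlap_length: int = 0
    gap: int = 0


def classify_region_relation(
    degron: SequenceRegion,
    site: SequenceRegion,
    window: int = DEFAULT_ADJACENCY_WINDOW,
) -> tuple[Relation, int, int]:
    """Classify a binding site's position relative to a degron.

    Returns ``(relation, overlap_length, gap)``.  Two regions overlap when
    they share at least one residue; disjoint regions are *adjacent* when the
    number of residues strictly between them (the gap) is between 1 and
    ``window``; otherwise the relation is ``none``.

    Raises ``ValueError`` if the two regions are on different proteins.
    """
    if degron.protein_id != site.protein_id:
        raise ValueError(
            f"regions on different proteins: {degron.protein_id!r} vs {site.protein_id!r}"
        )
    lo = max(degron.start, site.start)
    hi = min(degron.end, site.end)
    if lo <= hi:
        return Relation.OVERLAP, hi - lo + 1, 0
    # disjoint: gap = residues strictly between the two intervals
    if degron.end < site.start:
        gap = site.start - degron.end - 1
    else:
        gap = degron.start - site.end - 1
    if 1 <= gap <= window:
        return Relation.ADJACENT, 0, gap
    return Relation.NONE, 0, gap


def filter_interaction_records(
    records: Sequence[BindingFeature],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[BindingFeature]:
    """Keep only features of interaction pairs whose confidence passes the cutoff.

    Retention is per interaction pair: if any feature record of a
    (substrate, partner) pair carries a confidence below ``min_confidence``
    the pair's maximum confidence decides, so that all features of a dropped
    pair are dropped together.
    """
    pair_conf: dict[tuple[str, str], float] = {}
    for rec in records:
        key = (rec.substrate_id, rec.partner_id)
        pair_conf[key] = max(pair_conf.get(key, 0.0), rec.confidence)
    kept = [
        rec
        for rec in records
        if pair_conf[(rec.substrate_id, rec.partner_id)] >= min_confidence
    ]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("confidence filter dropped %d/%d feature records", dropped, len(records))
    return kept


def filter_ups_partners(
    partners: Iterable[str],
    annotations: Mapping[str, set[str]],
    blacklist: set[str],
    dag,
) -> list[str]:
    """Remove partners annotated with ubiquitin–proteasome-system GO terms.

    A partner is removed iff any of its annotated terms is a blacklist term
    or a descendant of one in the ontology ``dag`` (a :class:`~degronon.semsim.GoDag`).
    Raises ``ValueError`` for blacklist terms absent from the DAG.
    """
    unknown = blacklist - set(dag.terms)
    if unknown:
        raise ValueError(f"blacklist terms not in ontology: {sorted(unknown)}")
    closed = set(blacklist)
    for term in blacklist:
        closed |= dag.descendants(term)
    retained, removed = [], []
    for p in partners:
        terms = annotations.get(p, set())
        (removed if terms & closed else retained).append(p)
    if removed:
        logger.info("UPS filter removed %d partners: %s", len(removed), sorted(removed))
    return retained


def infer_tertiary_degron(
    profile: Sequence[float],
    ubsite: int,
    min_run: int = 20,
    threshold: float = 0.5,
    protein_id: str = "",
) -> Optional[SequenceRegion]:
    """Infer the tertiary degron from a per-residue disorder profile.

    The tertiary degron is taken to be the intrinsically disordered region
    nearest in sequence to the ubiquitination site that contains at least
    ``min_run`` consecutive residues with disorder score >= ``threshold``.
    Runs are maximal; a run containing the Ubsite has distance 0.  Ties in
    distance resolve to the upstream (lower-coordinate) run.  Returns ``None``
    when no qualifying run exists.

    ``profile[i]`` is the score of residue ``i+1`` (1-based coordinates).
    """
    n = len(profile)
    if not (1 <= ubsite <= n):
        raise ValueError(f"ubsite {ubsite} outside profile of length {n}")
    runs: list[tuple[int, int]] = []
    start = None
    for i, score in enumerate(profile):
        if score >= threshold:
            if start is None:
                start = i + 1
        else:
            if start is not None and (i + 1 - start) >= min_run:
                runs.append((start, i))
            start = None
    if start is not None and (n + 1 - start) >= min_run:
        runs.append((start, n))
    if not runs:
        return None

    def distance(run: tuple[int, int]) -> int:
        s, e = run
        if s <= ubsite <= e:
            return 0
        return s - ubsite if s > ubsite else ubsite - e

    # min() on (distance, start) implements the upstream tie-break
    best = min(runs, key=lambda r: (distance(r), r[0]))
    return SequenceRegion(protein_id, best[0], best[1])


@dataclass
class CensusRow:
    substrate_id: str
    n_partners_total: int
    n_masking: dict[DegronClass, int] = field(default_factory=dict)
    n_masking_overlap_only: dict[DegronClass, int] = field(default_factory=dict)


def masking_pairs(
    degrons: Sequence[DegronAnnotation],
    features: Sequence[BindingFeature],
    window: int = DEFAULT_ADJACENCY_WINDOW,
    include_adjacent: bool = True,
) -> set[tuple[str, str]]:
    """The set of (substrate, partner) pairs with at least one masking feature."""
    pairs: set[tuple[str, str]] = set()
    by_protein: dict[str, list[DegronAnnotation]] = defaultdict(list)
    for d in degrons:
        by_protein[d.region.protein_id].append(d)
    for feat in features:
        for deg in by_protein.get(feat.substrate_id, []):
            rel, _, _ = classify_region_relation(deg.region, feat.region, window)
            if rel is Relation.OVERLAP or (include_adjacent and rel is Relation.ADJACENT):
                pairs.add((feat.substrate_id, feat.partner_id))
                break
    return pairs


def masking_census(
    substrate_partners: Mapping[str, set[str]],
    degrons: Sequence[DegronAnnotation],
    features: Sequence[BindingFeature],
    window: int = DEFAULT_ADJACENCY_WINDOW,
    include_adjacent: bool = True,
    label_threshold: int = 10,
) -> tuple[list[CensusRow], list[int], list[str]]:
    """Per-substrate census of total vs degron-masking partners.

    ``substrate_partners`` maps each substrate to its full partner set
    (partners without feature annotations count toward the total but can
    never be masking).  A partner counts as masking for a degron class when
    at least one of its features overlaps (or, when ``include_adjacent``,
    lies within ``window`` residues of) a degron of that class; each partner
    counts once per (substrate, degron class).

    Returns ``(rows, masking_segment_lengths, labeled_substrates)`` where
    ``labeled_substrates`` are those with at least ``label_threshold`` masking
    partners for any degron class and ``masking_segment_lengths`` collects the
    lengths of all degron-masking binding segments.
    """
    by_protein: dict[str, list[DegronAnnotation]] = defaultdict(list)
    for d in degrons:
        by_protein[d.region.protein_id].append(d)

    masking: dict[tuple[str, DegronClass], set[str]] = defaultdict(set)
    overlap_only: dict[tuple[str, DegronClass], set[str]] = defaultdict(set)
    seg_lengths: list[int] = []
    for feat in features:
        feat_masks = False
        for deg in by_protein.get(feat.substrate_id, []):
            rel, _, _ = classify_region_relation(deg.region, feat.region, window)
            if rel is Relation.OVERLAP:
                overlap_only[(feat.substrate_id, deg.degron_class)].add(feat.partner_id)
            if rel is Relation.OVERLAP or (include_adjacent and rel is Relation.ADJACENT):
                masking[(feat.substrate_id, deg.degron_class)].add(feat.partner_id)
                feat_masks = True
        if feat_masks:
            seg_lengths.append(len(feat.region))

    rows: list[CensusRow] = []
    labeled: list[str] = []
    for sub in sorted(substrate_partners):
        row = CensusRow(sub, len(substrate_partners[sub]))
        for cls in DegronClass:
            row.n_masking[cls] = len(masking.get((sub, cls), set()))
            row.n_masking_overlap_only[cls] = len(overlap_only.get((sub, cls), set()))
        rows.append(row)
        if any(v >= label_threshold for v in row.n_masking.values()):
            labeled.append(sub)
    return rows, seg_lengths, labeled


def motif_category_census(
    motifs: Sequence[MotifAnnotation],
    degrons: Sequence[DegronAnnotation],
    window: int = DEFAULT_ADJACENCY_WINDOW,
) -> Counter:
    """Count degron-overlapping/adjacent motifs per (degron class, category).

    Uses the same relation classifier and adjacency window as binding
    features; motifs with relation ``none`` to every degron are excluded.
    """
    by_protein: dict[str, list[DegronAnnotation]] = defaultdict(list)
    for d in degrons:
        by_protein[d.region.protein_id].append(d)
    counts: Counter = Counter()
    for motif in motifs:
        for deg in by_protein.get(motif.region.protein_id, []):
            rel, _, _ = classify_region_relation(deg.region, motif.region, window)
            if rel is not Relation.NONE:
                counts[(deg.degron_class, motif.category)] += 1
    return counts
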