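"""Synthetic data generation with known ground truth.

Emulates all inputs the pipeline consumes: substrates carrying tripartite
degrons with disorder profiles, interaction records with masking and
non-masking binding features plus a two-component confidence mixture, a
Biological Process ontology with planted module-specific branches and a UPS
branch, PaxDb-style abundance datasets with role-ordered medians summing to
~10^6 ppm, and a protein interaction network with planted co-degrading
modules (shared half-lives, shared GO terms, high co-expression) against a
random background.

Every generator operation draws from its own RNG stream derived from the
master seed, so adding or re-running one generator never perturbs another's
output; identical configs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .abundance import AbundanceDataset, DatasetCategory, Role
from .io import InteractionRecord
from .masking import (
    DegronAnnotation,
    DegronClass,
    FeatureKind,
    Provenance,
    SequenceRegion,
    classify_region_relation,
    Relation,
)
from .network import HalfLifeTable, HalfLifeUnits

AMINO_ACIDS = "ACDEFGHILMNPQRSTVWY"  # K handled separately (Ubsites)

# RNG stream indices, one per generator operation
_STREAM_SUBSTRATES = 1
_STREAM_INTERACTIONS = 2
_STREAM_GO = 3
_STREAM_ABUNDANCE = 4
_STREAM_NETWORK = 5

UPS_ROOT_TERM = "GO:9000000"  # root of the synthetic UPS branch


@dataclass
class SynthConfig:
    seed: int = 0
    n_substrates: int = 20
    n_partners_per_substrate: int = 10
    masking_fraction: float = 0.5
    n_datasets: int = 50
    role_median_log_ppm: dict = field(
        default_factory=lambda: {"substrate": 1.5, "e3": 1.0, "ap": 2.0}
    )
    e3_ap_fold: float = 10.0
    n_modules: int = 5
    module_size: int = 8
    n_background: int = 500
    within_module_halflife_cv: float = 0.05
    background_halflife_logsd: float = 0.6
    within_module_coexpr: float = 0.8
    semsim_shared_terms: int = 3
    # generator knobs beyond the planted effect sizes
    low_confidence_fraction: float = 0.1
    ups_partner_fraction: float = 0.1
    n_chords_per_module: int = 1
    substrate_e3_latent_sd: float = 0.3  # dataset-level coupling of substrate and E3
    background_edge_factor: float = 2.0  # background edges = factor * n_background
    disorder_threshold: float = 0.5
    adjacency_window: int = 10

    def __post_init__(self) -> None:
        counts = {
            "n_substrates": self.n_substrates,
            "n_partners_per_substrate": self.n_partners_per_substrate,
            "n_datasets": self.n_datasets,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "n_background": self.n_background,
            "semsim_shared_terms": self.semsim_shared_terms,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name, v in [
            ("masking_fraction", self.masking_fraction),
            ("within_module_coexpr", self.within_module_coexpr),
            ("low_confidence_fraction", self.low_confidence_fraction),
            ("ups_partner_fraction", self.ups_partner_fraction),
        ]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.e3_ap_fold <= 1:
            raise ValueError("e3_ap_fold must be > 1")
        if self.within_module_halflife_cv < 0:
            raise ValueError("within_module_halflife_cv must be >= 0")
        if self.module_size < 2:
            raise ValueError("module_size must be >= 2")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    module_membership: dict[str, str] = field(default_factory=dict)  # "" = background
    masking_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_degronon_paths: list[list[str]] = field(default_factory=list)


def _substrate_id(i: int) -> str:
    return f"S{i:03d}"


def _module_node(m: int, i: int) -> str:
    return f"M{m:02d}_{i:02d}"


def _background_node(i: int) -> str:
    return f"B{i:04d}"


# ----------------------------------------------------- substrates & degrons


def gen_substrates_with_degrons(
    cfg: SynthConfig,
) -> tuple[dict[str, str], list[DegronAnnotation], dict[str, list[float]]]:
    """Substrates with one primary degron, one Ubsite (secondary degron) and
    a planted disordered tract recorded as the true tertiary degron.

    Returns ``(sequences, degrons, disorder_profiles)``.  Profiles are
    piecewise-constant blocks (disordered ~0.8, ordered ~0.2) with additive
    noise clipped to [0,1]; the disordered block nearest the Ubsite spans at
    least 20 residues and is emitted as a tertiary degron with provenance
    ``inferred``.  An optional decoy disordered block is placed strictly
    farther from the Ubsite.
    """
    rng = cfg.rng(_STREAM_SUBSTRATES)
    sequences: dict[str, str] = {}
    degrons: list[DegronAnnotation] = []
    profiles: dict[str, list[float]] = {}
    for i in range(cfg.n_substrates):
        sid = _substrate_id(i)
        length = int(rng.integers(200, 801))
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))

        # primary degron in the first third
        deg_len = int(rng.integers(6, 15))
        p_start = int(rng.integers(10, length // 3 - deg_len))
        p_end = p_start + deg_len - 1
        degrons.append(
            DegronAnnotation(
                region=SequenceRegion(sid, p_start, p_end),
                degron_class=DegronClass.PRIMARY,
                sequence="".join(seq[p_start - 1 : p_end]),
                provenance=Provenance.EXPERIMENTAL,
            )
        )

        # Ubsite lysine in the middle third; secondary degron = that residue
        ubsite = int(rng.integers(length // 3 + 15, 2 * length // 3 - 15))
        seq[ubsite - 1] = "K"
        degrons.append(
            DegronAnnotation(
                region=SequenceRegion(sid, ubsite, ubsite),
                degron_class=DegronClass.SECONDARY,
                sequence="K",
                ubsite_position=ubsite,
                provenance=Provenance.EXPERIMENTAL,
            )
        )

        # disordered block containing the Ubsite (distance 0 => nearest)
        run_len = int(rng.integers(20, 41))
        offset = int(rng.integers(0, run_len))
        t_start = max(1, ubsite - offset)
        t_end = min(length, t_start + run_len - 1)
        if t_end - t_start + 1 < 20:  # clipped at the C-terminus
            t_start = t_end - 19
        profile = np.full(length, 0.2) + rng.uniform(-0.1, 0.1, size=length)
        profile[t_start - 1 : t_end] = 0.8 + rng.uniform(-0.1, 0.1, size=t_end - t_start + 1)
        # decoy disordered block in the final quarter, strictly farther away
        if rng.random() < 0.5:
            d_len = int(rng.integers(20, 31))
            d_start = int(rng.integers(3 * length // 4, length - d_len))
            if (d_start - ubsite) > max(ubsite - t_start, t_end - ubsite) and d_start > t_end + 2:
                profile[d_start - 1 : d_start + d_len - 1] = 0.8 + rng.uniform(
                    -0.1, 0.1, size=d_len
                )
        profile = np.clip(profile, 0.0, 1.0)
        degrons.append(
            DegronAnnotation(
                region=SequenceRegion(sid, t_start, t_end),
                degron_class=DegronClass.TERTIARY,
                provenance=Provenance.INFERRED,
            )
        )
        sequences[sid] = "".join(seq)
        profiles[sid] = [float(x) for x in profile]
    return sequences, degrons, profiles


# -------------------------------------------------------- interaction records


def gen_interaction_records(
    cfg: SynthConfig,
    sequences: dict[str, str],
    degrons: Sequence[DegronAnnotation],
) -> tuple[list[InteractionRecord], set[tuple[str, str]], set[str]]:
    """Interaction records with planted masking / non-masking features.

    A ``masking_fraction`` of each substrate's partners carries a binding
    feature overlapping one of its degrons; the rest carry a feature at a
    degron-free location or no feature at all.  Confidence scores come from
    a two-component mixture (a ``low_confidence_fraction`` of pairs scores
    below 0.3); a ``ups_partner_fraction`` of partners is flagged as
    UPS-related (to be annotated with blacklist GO terms downstream).

    Returns ``(records, masking_pairs, ups_partners)`` where
    ``masking_pairs`` is the *recoverable* ground truth: planted masking
    pairs that pass the confidence cutoff and are not UPS-flagged.
    """
    rng = cfg.rng(_STREAM_INTERACTIONS)
    by_sub: dict[str, list[DegronAnnotation]] = {}
    for d in degrons:
        by_sub.setdefault(d.region.protein_id, []).append(d)

    records: list[InteractionRecord] = []
    masking_pairs: set[tuple[str, str]] = set()
    ups_partners: set[str] = set()
    n_int = 0
    for sid in sorted(sequences):
        length = len(sequences[sid])
        subs_degrons = by_sub.get(sid, [])
        for k in range(cfg.n_partners_per_substrate):
            pid = f"{sid}_P{k:02d}"
            n_int += 1
            is_masking = rng.random() < cfg.masking_fraction
            is_low_conf = rng.random() < cfg.low_confidence_fraction
            is_ups = rng.random() < cfg.ups_partner_fraction
            confidence = (
                float(rng.uniform(0.05, 0.25))
                if is_low_conf
                else float(rng.uniform(0.4, 1.0))
            )
            features: list[tuple[FeatureKind, int, int]] = []
            if is_masking and subs_degrons:
                target = subs_degrons[int(rng.integers(0, len(subs_degrons)))]
                span = int(rng.integers(8, 40))
                jitter = int(rng.integers(-5, 6))
                start = max(1, min(length - span + 1, target.region.start + jitter))
                end = min(length, start + span - 1)
                kind = FeatureKind(
                    [
                        FeatureKind.SUFFICIENT_BINDING_REGION,
                        FeatureKind.BINDING_ASSOCIATED_REGION,
                        FeatureKind.NECESSARY_BINDING_REGION,
                        FeatureKind.MUTATION_EVIDENCE,
                    ][int(rng.integers(0, 4))]
                )
                features.append((kind, start, end))
                if not is_low_conf and not is_ups:
                    masking_pairs.add((sid, pid))
            elif rng.random() < 0.5:
                # non-masking feature: rejection-sample a degron-free spot
                for _ in range(200):
                    span = int(rng.integers(8, 31))
                    start = int(rng.integers(1, max(2, length - span)))
                    region = SequenceRegion(sid, start, start + span - 1)
                    if all(
                        classify_region_relation(d.region, region, cfg.adjacency_window)[0]
                        is Relation.NONE
                        for d in subs_degrons
                    ):
                        features.append(
                            (FeatureKind.SUFFICIENT_BINDING_REGION, region.start, region.end)
                        )
                        break
            if is_ups:
                ups_partners.add(pid)
            records.append(
                InteractionRecord(
                    substrate_id=sid,
                    partner_id=pid,
                    interaction_id=f"INT-{n_int:05d}",
                    confidence=confidence,
                    features=features,
                )
            )
    return records, masking_pairs, ups_partners


# --------------------------------------------------------------- GO ontology


def gen_go_dag_and_annotations(
    cfg: SynthConfig,
    ups_partners: Sequence[str] = (),
) -> tuple[list[str], list[tuple[str, str, str]], dict[str, str], list[tuple[str, str, str]]]:
    """A synthetic Biological Process ontology plus gene annotations.

    The DAG has one BP root; each planted module gets its own branch whose
    ``semsim_shared_terms`` leaf terms are shared by all module members
    (IDA evidence).  Background genes are annotated into per-gene leaf terms
    under a diverse background branch, so background pairs have low
    similarity.  A dedicated UPS branch supplies blacklist terms; any
    ``ups_partners`` are annotated into it.  A sprinkling of IEA records
    exercises the evidence filter.

    Returns ``(terms, edges, namespace, annotation_records)`` with edges as
    (child, parent, relation) and annotations as (gene, term, evidence_code).
    """
    rng = cfg.rng(_STREAM_GO)
    root = "GO:0000001"
    terms = [root]
    edges: list[tuple[str, str, str]] = []
    annotations: list[tuple[str, str, str]] = []
    counter = 2

    def new_term(parent: str, rel: str = "is_a") -> str:
        nonlocal counter
        t = f"GO:{counter:07d}"
        counter += 1
        terms.append(t)
        edges.append((t, parent, rel))
        return t

    # module branches: root -> module parent -> shared leaf terms
    for m in range(cfg.n_modules):
        branch = new_term(root)
        mid = new_term(branch)  # intermediate level for graph depth
        shared = [
            new_term(mid, "is_a" if rng.random() < 0.7 else "part_of")
            for _ in range(cfg.semsim_shared_terms)
        ]
        for i in range(cfg.module_size):
            gene = _module_node(m, i)
            for t in shared:
                annotations.append((gene, t, "IDA"))
            # an IEA record that the evidence filter must drop
            annotations.append((gene, branch, "IEA"))

    # background branch: per-gene leaves under rotating sub-branches
    bg_root = new_term(root)
    bg_branches = [new_term(bg_root) for _ in range(10)]
    for i in range(cfg.n_background):
        gene = _background_node(i)
        branch = bg_branches[i % len(bg_branches)]
        leaf = new_term(branch)
        annotations.append((gene, leaf, "IDA" if rng.random() < 0.7 else "IPI"))

    # UPS branch: blacklist root with descendant terms
    terms.append(UPS_ROOT_TERM)
    edges.append((UPS_ROOT_TERM, root, "is_a"))
    ups_children = [new_term(UPS_ROOT_TERM) for _ in range(3)]
    for p in sorted(ups_partners):
        term = ups_children[int(rng.integers(0, len(ups_children)))]
        annotations.append((p, term, "IDA"))

    namespace = {t: "biological_process" for t in terms}
    return terms, edges, namespace, annotations


# --------------------------------------------------------- abundance datasets


def gen_abundance_datasets(
    cfg: SynthConfig,
    roles: dict[str, str],
    n_background_proteins: int = 1000,
) -> list[AbundanceDataset]:
    """PaxDb-style datasets with role-ordered log-normal abundances.

    Per dataset, log10 ppm for a protein of role r is drawn Normal around
    ``role_median_log_ppm[r]`` (the AP median sits ``log10(e3_ap_fold)``
    above the E3 median by default); substrates and E3s share a dataset-level
    latent factor that induces cross-dataset correlation.  Background filler
    proteins complete the proteome and every dataset is renormalized to a ppm
    total of exactly 10^6.
    """
    rng = cfg.rng(_STREAM_ABUNDANCE)
    categories = list(DatasetCategory)
    datasets: list[AbundanceDataset] = []
    proteins = sorted(roles)
    for d in range(cfg.n_datasets):
        latent = rng.normal(0.0, cfg.substrate_e3_latent_sd)  # shared substrate/E3 factor
        abundances: dict[str, float] = {}
        for p in proteins:
            role = roles[p]
            mu = cfg.role_median_log_ppm[role]
            shift = latent if role in ("substrate", "e3") else 0.0
            abundances[p] = 10 ** (mu + shift + rng.normal(0.0, 0.4))
        for b in range(n_background_proteins):
            abundances[f"BGP{b:04d}"] = 10 ** rng.normal(1.5, 0.8)
        total = sum(abundances.values())
        scale = 1_000_000.0 / total
        abundances = {p: v * scale for p, v in abundances.items()}
        datasets.append(
            AbundanceDataset(
                dataset_id=f"DS{d:03d}",
                abundances=abundances,
                category=categories[d % len(categories)],
            )
        )
    return datasets


# ------------------------------------------------------ co-degradation network


def gen_codegradation_network(
    cfg: SynthConfig,
) -> tuple[nx.Graph, HalfLifeTable, dict[frozenset, float], GroundTruth]:
    """A PPI network with planted co-degrading modules and random background.

    Each module is a backbone chain of ``module_size`` nodes (the planted
    degronon path) plus ``n_chords_per_module`` chord edges of span 2.
    Module members draw half-lives around a shared module mean with
    coefficient of variation ``within_module_halflife_cv``; background nodes
    get independent log-normal half-lives (sd ``background_halflife_logsd``
    on the natural-log scale).  Within-module pair co-expression centers on
    ``within_module_coexpr``; background pair co-expression centers on zero.
    """
    rng = cfg.rng(_STREAM_NETWORK)
    net = nx.Graph()
    truth = GroundTruth()
    halflives: dict[str, float] = {}
    coexpr: dict[frozenset, float] = {}

    for m in range(cfg.n_modules):
        members = [_module_node(m, i) for i in range(cfg.module_size)]
        for u, v in zip(members, members[1:]):
            net.add_edge(u, v)
        for _ in range(cfg.n_chords_per_module):
            if cfg.module_size >= 3:
                i = int(rng.integers(0, cfg.module_size - 2))
                net.add_edge(members[i], members[i + 2])
        truth.planted_degronon_paths.append(members)
        for node in members:
            truth.module_membership[node] = f"module_{m}"
        mean = float(np.exp(rng.normal(np.log(60.0), 0.5)))
        for node in members:
            halflives[node] = max(
                1e-3, mean * (1.0 + cfg.within_module_halflife_cv * rng.normal())
            )
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                r = cfg.within_module_coexpr + rng.normal(0.0, 0.05)
                coexpr[frozenset((u, v))] = float(np.clip(r, -1.0, 1.0))

    bg_nodes = [_background_node(i) for i in range(cfg.n_background)]
    net.add_nodes_from(bg_nodes)
    for node in bg_nodes:
        truth.module_membership[node] = ""
        halflives[node] = float(np.exp(rng.normal(np.log(60.0), cfg.background_halflife_logsd)))
    n_bg_edges = int(cfg.background_edge_factor * cfg.n_background)
    added = 0
    attempts = 0
    while added < n_bg_edges and attempts < 50 * n_bg_edges:
        attempts += 1
        u, v = rng.choice(len(bg_nodes), size=2, replace=False)
        a, b = bg_nodes[int(u)], bg_nodes[int(v)]
        if not net.has_edge(a, b):
            net.add_edge(a, b)
            coexpr[frozenset((a, b))] = float(np.clip(rng.normal(0.0, 0.1), -1.0, 1.0))
            added += 1
    # one attachment edge per module so modules sit inside the big network;
    # a single attachment cannot create alternative in-module shortest paths
    for m in range(cfg.n_modules):
        anchor = _module_node(m, 0)
        target = bg_nodes[int(rng.integers(0, len(bg_nodes)))]
        net.add_edge(anchor, target)
        coexpr[frozenset((anchor, target))] = float(
            np.clip(rng.normal(0.0, 0.1), -1.0, 1.0)
        )

    table = HalfLifeTable(values=halflives, units=HalfLifeUnits.RELATIVE, dataset_tag="synthetic")
    return net, table, coexpr, truth


def gen_regulatory_modules(
    cfg: SynthConfig,
    masking_pairs: set[tuple[str, str]],
):
    """Degradation-regulatory modules implied by the masking ground truth.

    Each substrate gets one synthetic E3 ligase (``<sid>_E3``) and its
    planted masking partners as alternate partners (APs).  Returns
    ``(modules, roles)`` with roles mapping protein -> 'substrate'|'e3'|'ap'.
    """
    from .abundance import RegulatoryModule

    aps_by_sub: dict[str, set[str]] = {}
    for sid, pid in masking_pairs:
        aps_by_sub.setdefault(sid, set()).add(pid)
    modules = []
    roles: dict[str, str] = {}
    for i in range(cfg.n_substrates):
        sid = _substrate_id(i)
        e3 = f"{sid}_E3"
        aps = aps_by_sub.get(sid, set())
        modules.append(RegulatoryModule(substrate=sid, e3s={e3}, aps=set(aps)))
        roles[sid] = "substrate"
        roles[e3] = "e3"
        for ap in aps:
            roles[ap] = "ap"
    return modules, roles


def module_semsim_table(cfg: SynthConfig, truth: GroundTruth) -> dict[frozenset, float]:
    """Shortcut pairwise similarity table consistent with the planted GO
    structure: 1.0 within a module, ~0 elsewhere.  Useful for tests that
    exercise the network module without recomputing Wang similarity."""
    out: dict[frozenset, float] = {}
    members: dict[str, list[str]] = {}
    for node, mod in truth.module_membership.items():
        if mod:
            members.setdefault(mod, []).append(node)
    for mod, nodes in members.items():
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                out[frozenset((u, v))] = 1.0
    return out
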