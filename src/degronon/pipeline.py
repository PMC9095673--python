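"""End-to-end orchestration of the degron-masking / degronon pipeline.

Stages run in dependency order: ``simulate -> mask -> semsim -> abundance ->
network``.  Every stage writes machine-readable outputs (TSV + JSON) into
the configured output directory, tagged with provenance metadata (config
hash, seed, package version).  Reruns with the same config are idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as dio
from .abundance import (
    RegulatoryModule,
    module_rank_heatmap,
    role_abundance_comparison,
    substrate_partner_correlation,
)
from .masking import masking_census, masking_pairs as compute_masking_pairs
from .network import (
    build_pair_records,
    category_fractions,
    degree_halflife_correlation,
    detect_degronons,
    ratio_distribution_vs_random,
    shortest_path_ratio_profile,
    validate_network,
)
from .semsim import GoDag, PairwiseSemSim, filter_annotations
from .synth import (
    SynthConfig,
    UPS_ROOT_TERM,
    gen_abundance_datasets,
    gen_codegradation_network,
    gen_go_dag_and_annotations,
    gen_interaction_records,
    gen_regulatory_modules,
    gen_substrates_with_degrons,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

STAGES = ("simulate", "mask", "semsim", "abundance", "network")

STAGE_DEPS = {
    "simulate": (),
    "mask": ("simulate",),
    "semsim": ("simulate",),
    "abundance": ("simulate",),
    "network": ("simulate", "semsim"),
}


class DependencyError(RuntimeError):
    """A stage's upstream outputs are missing."""


@dataclass
class PipelineConfig:
    out_dir: str = "degronon_out"
    seed: int = 0
    min_confidence: float = 0.3
    adjacency_window: int = 10
    disorder_threshold: float = 0.5
    min_idr_run: int = 20
    semsim_cutoff: float = 0.6
    degronon_min_length: int = 6
    n_random: int = 10
    n_bins: int = 100
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        for name in (
            "min_confidence",
            "adjacency_window",
            "disorder_threshold",
            "min_idr_run",
            "semsim_cutoff",
            "degronon_min_length",
            "n_random",
            "n_bins",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", {})
        cfg = cls(**raw, synth=SynthConfig(**synth_raw))
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "config_hash": self.config_hash(),
            "seed": self.seed,
        }


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage '{stage}' requires missing output: {path}")
    return path


def run_simulate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth = cfg.synth
    sequences, degrons, profiles = gen_substrates_with_degrons(synth)
    records, mask_truth, ups_partners = gen_interaction_records(synth, sequences, degrons)
    terms, edges, namespace, annotations = gen_go_dag_and_annotations(
        synth, ups_partners=sorted(ups_partners)
    )
    modules, roles = gen_regulatory_modules(synth, mask_truth)
    datasets = gen_abundance_datasets(synth, roles)
    net, halflives, coexpr, truth = gen_codegradation_network(synth)

    dio.write_degron_table(degrons, out / "degrons.tsv")
    dio.write_mitab(records, out / "interactions.mitab.tsv")
    dio.write_disorder_dir(profiles, out / "disorder")
    dio.write_obo(terms, edges, namespace, out / "ontology.obo")
    dio.write_gaf(annotations, out / "annotations.tsv")
    paxdir = out / "paxdb"
    paxdir.mkdir(exist_ok=True)
    for ds in datasets:
        dio.write_paxdb(ds, paxdir / f"{ds.dataset_id}.tsv")
    dio.write_edge_list(sorted(tuple(sorted(e)) for e in net.edges()), out / "edges.tsv")
    dio.write_halflife_table(halflives, out / "halflife.tsv")
    dio.write_coexpression(coexpr, out / "coexpression.tsv")
    with open(out / "modules.json", "w") as fh:
        json.dump(
            [
                {"substrate": m.substrate, "e3s": sorted(m.e3s), "aps": sorted(m.aps)}
                for m in modules
            ],
            fh,
            indent=1,
        )
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "module_membership": truth.module_membership,
                "masking_pairs": sorted(map(list, mask_truth)),
                "ups_partners": sorted(ups_partners),
                "planted_degronon_paths": truth.planted_degronon_paths,
            },
            fh,
            indent=1,
        )
    return {
        "n_substrates": len(sequences),
        "n_interaction_records": len(records),
        "n_datasets": len(datasets),
        "network_nodes": net.number_of_nodes(),
        "network_edges": net.number_of_edges(),
    }


def run_mask(cfg: PipelineConfig, blacklist: Optional[set[str]] = None) -> dict:
    out = Path(cfg.out_dir)
    degrons = dio.read_degron_table(_require(out / "degrons.tsv", "mask"))
    records = dio.read_mitab(_require(out / "interactions.mitab.tsv", "mask"))
    dag = GoDag.from_obo(str(_require(out / "ontology.obo", "mask")))
    gaf = dio.read_gaf(_require(out / "annotations.tsv", "mask"))
    blacklist = blacklist or {UPS_ROOT_TERM}

    # confidence filter at the record level, then UPS filter at partner level
    features = [f for r in records for f in r.binding_features()]
    from .masking import filter_interaction_records, filter_ups_partners

    features = filter_interaction_records(features, cfg.min_confidence)
    annotations = {g: set() for g, _, _ in gaf}
    for g, t, _ in gaf:
        annotations[g].add(t)
    partners_all = {r.partner_id for r in records}
    kept_partners = set(
        filter_ups_partners(sorted(partners_all), annotations, blacklist, dag)
    )
    features = [f for f in features if f.partner_id in kept_partners]

    substrate_partners: dict[str, set[str]] = {}
    for r in records:
        if r.confidence >= cfg.min_confidence and r.partner_id in kept_partners:
            substrate_partners.setdefault(r.substrate_id, set()).add(r.partner_id)

    rows, seg_lengths, labeled = masking_census(
        substrate_partners, degrons, features, window=cfg.adjacency_window
    )
    pairs = compute_masking_pairs(degrons, features, window=cfg.adjacency_window)

    with open(out / "masking_census.tsv", "w") as fh:
        fh.write(
            "substrate_id\tn_partners_total\tn_masking_primary\tn_masking_secondary\t"
            "n_masking_tertiary\n"
        )
        for row in rows:
            vals = [row.n_masking[c] for c in list(row.n_masking)]
            fh.write(f"{row.substrate_id}\t{row.n_partners_total}\t" + "\t".join(map(str, vals)) + "\n")
    report = {
        "provenance": cfg.provenance(),
        "n_masking_pairs": len(pairs),
        "masking_pairs": sorted(map(list, pairs)),
        "labeled_substrates": labeled,
        "segment_length_median": float(np.median(seg_lengths)) if seg_lengths else None,
    }
    with open(out / "masking_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def run_semsim(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    dag = GoDag.from_obo(str(_require(out / "ontology.obo", "semsim")))
    gaf = dio.read_gaf(_require(out / "annotations.tsv", "semsim"))
    net = dio.read_edge_list(_require(out / "edges.tsv", "semsim"))
    annotations = filter_annotations(gaf, dag)
    calc = PairwiseSemSim(annotations, dag)
    sims = calc.all_pairs(net.nodes())
    dio.write_semsim_pairs(sims, out / "semsim_pairs.tsv")
    return {
        "provenance": cfg.provenance(),
        "n_pairs": len(sims),
        "n_annotated_genes": len(set(annotations) & set(net.nodes())),
    }


def run_abundance(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    paxdir = _require(out / "paxdb", "abundance")
    datasets = [dio.read_paxdb(p) for p in sorted(paxdir.glob("*.tsv"))]
    with open(_require(out / "modules.json", "abundance")) as fh:
        modules = [
            RegulatoryModule(m["substrate"], set(m["e3s"]), set(m["aps"]))
            for m in json.load(fh)
        ]
    comp = role_abundance_comparison(datasets, modules)
    r_e3, p_e3, n_e3 = substrate_partner_correlation(modules, datasets, mode="per_e3")
    r_ap, p_ap, n_ap = substrate_partner_correlation(modules, datasets, mode="summed_aps")
    proteins = sorted(
        {m.substrate for m in modules}
        | {e for m in modules for e in m.e3s}
        | {a for m in modules for a in m.aps}
    )
    heat = module_rank_heatmap(proteins, datasets, n_bins=cfg.n_bins)
    heat.to_csv(out / "rank_heatmap.tsv", sep="\t", na_rep="NA")
    report = {
        "provenance": cfg.provenance(),
        "medians": {r.value: comp.medians[r] for r in comp.medians},
        "n": {r.value: comp.n[r] for r in comp.n},
        "pvalues": {f"{a.value}_vs_{b.value}": p for (a, b), p in comp.pvalues.items()},
        "substrate_e3_spearman": {"r": r_e3, "p": p_e3, "n": n_e3},
        "substrate_summed_ap_spearman": {"r": r_ap, "p": p_ap, "n": n_ap},
    }
    with open(out / "abundance_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


def run_network(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    net = validate_network(dio.read_edge_list(_require(out / "edges.tsv", "network")))
    halflives = dio.read_halflife_table(_require(out / "halflife.tsv", "network"))
    semsim = dio.read_semsim_pairs(_require(out / "semsim_pairs.tsv", "network"))
    coexpr = dio.read_coexpression(_require(out / "coexpression.tsv", "network"))

    records = build_pair_records(net, halflives, semsim=semsim, coexpression=coexpr)
    env = ratio_distribution_vs_random(net, halflives, n_random=cfg.n_random, seed=cfg.seed)
    profile = shortest_path_ratio_profile(net, halflives, max_len=cfg.degronon_min_length)
    degronons, all_ratios, high_ratios = detect_degronons(
        net,
        halflives,
        semsim,
        cutoff=cfg.semsim_cutoff,
        min_length=cfg.degronon_min_length,
    )
    corr = degree_halflife_correlation(net, halflives)

    with open(out / "pair_records.tsv", "w") as fh:
        fh.write("id_a\tid_b\thalf_life_ratio\tcategory\tsemsim\tcoexpression\n")
        for r in records:
            fh.write(
                f"{r.pair[0]}\t{r.pair[1]}\t{r.half_life_ratio:.4f}\t{r.category.value}\t"
                f"{'' if r.semsim is None else f'{r.semsim:.4f}'}\t"
                f"{'' if r.coexpression is None else f'{r.coexpression:.4f}'}\n"
            )
    report = {
        "provenance": cfg.provenance(),
        "half_life_dataset": halflives.dataset_tag,
        "n_pair_records": len(records),
        "category_fractions": {c.value: f for c, f in category_fractions(records).items()},
        "observed_similar_fraction": env.observed_similar_fraction,
        "random_similar_mean": env.random_similar_mean,
        "random_similar_sd": env.random_similar_sd,
        "path_profile_medians": {
            k: (float(np.median(v)) if v.size else None) for k, v in profile.items()
        },
        "degronons": [
            {
                "members": d.members,
                "length": d.length,
                "semsim_vs_first": d.semsim_vs_first,
                "ratio_vs_first": d.ratio_vs_first,
            }
            for d in degronons
        ],
        "degree_halflife_spearman": {k: list(v) for k, v in corr.items()},
    }
    with open(out / "network_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


_RUNNERS = {
    "simulate": run_simulate,
    "mask": run_mask,
    "semsim": run_semsim,
    "abundance": run_abundance,
    "network": run_network,
}


def run_pipeline(cfg: PipelineConfig, stages: Optional[Sequence[str]] = None) -> dict:
    """Run the requested stages in dependency order and bundle their reports."""
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in requested]
    results = {"provenance": cfg.provenance()}
    for stage in ordered:
        logger.info("running stage %s", stage)
        results[stage] = _RUNNERS[stage](cfg)
    write_report(results, Path(cfg.out_dir) / "report.json")
    return results


def write_report(results: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, default=float, sort_keys=True)
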