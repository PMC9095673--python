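"""Readers and writers for the pipeline's text formats.

Formats handled: degron annotation TSV, a PSI-MITAB 2.7 subset (tab-separated
interaction records with `intact-miscore` confidences and binding-feature
ranges), per-residue disorder profiles, OBO v1.2 ontologies (via obonet),
GAF-like gene-annotation TSV, PaxDb-style abundance TSV, PPI edge lists,
half-life tables and pairwise co-expression tables.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .abundance import AbundanceDataset, DatasetCategory
from .masking import (
    BindingFeature,
    DegronAnnotation,
    DegronClass,
    FeatureKind,
    MotifAnnotation,
    MotifCategory,
    Provenance,
    SequenceRegion,
)
from .network import HalfLifeTable, HalfLifeUnits

logger = logging.getLogger(__name__)


@dataclass
class InteractionRecord:
    """One substrate-partner interaction with optional binding features."""

    substrate_id: str
    partner_id: str
    interaction_id: str
    confidence: float
    features: list[tuple[FeatureKind, int, int]] = field(default_factory=list)

    def binding_features(self) -> list[BindingFeature]:
        return [
            BindingFeature(
                substrate_id=self.substrate_id,
                partner_id=self.partner_id,
                region=SequenceRegion(self.substrate_id, start, end),
                feature_kind=kind,
                confidence=self.confidence,
                interaction_id=self.interaction_id,
            )
            for kind, start, end in self.features
        ]


# ---------------------------------------------------------------- degron TSV

DEGRON_HEADER = "substrate_id\tclass\tstart\tend\tsequence\tubsite_position\tprovenance"


def write_degron_table(degrons: Sequence[DegronAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(DEGRON_HEADER + "\n")
        for d in degrons:
            fh.write(
                "\t".join(
                    [
                        d.region.protein_id,
                        d.degron_class.value,
                        str(d.region.start),
                        str(d.region.end),
                        d.sequence or "",
                        str(d.ubsite_position) if d.ubsite_position else "",
                        d.provenance.value,
                    ]
                )
                + "\n"
            )


def read_degron_table(path: str | Path) -> list[DegronAnnotation]:
    out: list[DegronAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                continue
            out.append(
                DegronAnnotation(
                    region=SequenceRegion(
                        parts[idx["substrate_id"]],
                        int(parts[idx["start"]]),
                        int(parts[idx["end"]]),
                    ),
                    degron_class=DegronClass(parts[idx["class"]]),
                    sequence=parts[idx["sequence"]] or None
                    if "sequence" in idx and len(parts) > idx["sequence"]
                    else None,
                    ubsite_position=int(parts[idx["ubsite_position"]])
                    if "ubsite_position" in idx and parts[idx["ubsite_position"]]
                    else None,
                    provenance=Provenance(parts[idx["provenance"]])
                    if "provenance" in idx and parts[idx["provenance"]]
                    else Provenance.EXPERIMENTAL,
                )
            )
    return out


# ------------------------------------------------------------- MITAB subset

MITAB_HEADER = "#id_a\tid_b\tinteraction_id\tconfidence\tfeatures_a"

_MISCORE_RE = re.compile(r"intact-miscore:([0-9.eE+-]+)")
_FEATURE_RE = re.compile(r"^([a-z_]+):(\S+)-(\S+)$")


def write_mitab(records: Sequence[InteractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(MITAB_HEADER + "\n")
        for r in records:
            feats = (
                "|".join(f"{k.value}:{s}-{e}" for k, s, e in r.features)
                if r.features
                else "-"
            )
            fh.write(
                f"{r.substrate_id}\t{r.partner_id}\t{r.interaction_id}\t"
                f"intact-miscore:{r.confidence:.4f}\t{feats}\n"
            )


def read_mitab(path: str | Path) -> list[InteractionRecord]:
    """Parse the MITAB subset; undetermined feature positions ('?' or 'n')
    skip that feature with a warning, unparseable confidences drop the record."""
    out: list[InteractionRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                logger.warning("skipping short MITAB line: %r", line[:80])
                continue
            id_a, id_b, iid, conf_field, feat_field = parts[:5]
            m = _MISCORE_RE.search(conf_field)
            if not m:
                logger.warning("unparseable confidence %r; record dropped", conf_field)
                continue
            confidence = float(m.group(1))
            features: list[tuple[FeatureKind, int, int]] = []
            if feat_field and feat_field != "-":
                for token in feat_field.split("|"):
                    fm = _FEATURE_RE.match(token)
                    if not fm:
                        logger.warning("unparseable feature %r skipped", token)
                        continue
                    kind, s, e = fm.groups()
                    if s in ("?", "n") or e in ("?", "n"):
                        logger.warning("undetermined feature position in %r skipped", token)
                        continue
                    try:
                        features.append((FeatureKind(kind), int(s), int(e)))
                    except (ValueError, KeyError):
                        logger.warning("unparseable feature %r skipped", token)
            out.append(InteractionRecord(id_a, id_b, iid, confidence, features))
    return out


# -------------------------------------------------------------- motif table

MOTIF_HEADER = "protein_id\tmotif_id\tcategory\tstart\tend"


def write_motif_table(motifs: Sequence[MotifAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(MOTIF_HEADER + "\n")
        for m in motifs:
            fh.write(
                f"{m.region.protein_id}\t{m.motif_id}\t{m.category.value}\t"
                f"{m.region.start}\t{m.region.end}\n"
            )


def read_motif_table(path: str | Path) -> list[MotifAnnotation]:
    out: list[MotifAnnotation] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            pid, mid, cat, s, e = line.rstrip("\n").split("\t")
            out.append(
                MotifAnnotation(
                    region=SequenceRegion(pid, int(s), int(e)),
                    category=MotifCategory(cat),
                    motif_id=mid,
                )
            )
    return out


# --------------------------------------------------------- disorder profiles


def write_disorder_profile(scores: Sequence[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tscore\n")
        for i, s in enumerate(scores, start=1):
            fh.write(f"{i}\t{s:.4f}\n")


def read_disorder_profile(path: str | Path) -> list[float]:
    scores: list[float] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            _, s = line.rstrip("\n").split("\t")
            scores.append(float(s))
    return scores


def write_disorder_dir(profiles: dict[str, Sequence[float]], dirpath: str | Path) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    for pid, scores in profiles.items():
        write_disorder_profile(scores, dirpath / f"{pid}.tsv")


def read_disorder_dir(dirpath: str | Path) -> dict[str, list[float]]:
    dirpath = Path(dirpath)
    return {
        p.stem: read_disorder_profile(p) for p in sorted(dirpath.glob("*.tsv"))
    }


# ----------------------------------------------------------------- OBO / GAF


def write_obo(
    terms: Sequence[str],
    edges: Sequence[tuple[str, str, str]],
    namespace: dict[str, str],
    path: str | Path,
    names: Optional[dict[str, str]] = None,
) -> None:
    """Write a minimal OBO v1.2 file readable by obonet."""
    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in terms}
    for child, parent, rel in edges:
        parents[child].append((parent, rel))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n\n")
        for t in terms:
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {(names or {}).get(t, t)}\n")
            fh.write(f"namespace: {namespace.get(t, 'biological_process')}\n")
            for parent, rel in parents[t]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")


GAF_HEADER = "gene\tterm\tevidence_code"


def write_gaf(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(GAF_HEADER + "\n")
        for gene, term, code in records:
            fh.write(f"{gene}\t{term}\t{code}\n")


def read_gaf(path: str | Path) -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("!", "#", "gene\t")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                logger.warning("malformed annotation line skipped: %r", line[:80])
                continue
            out.append((parts[0], parts[1], parts[2]))
    return out


# ------------------------------------------------------------- PaxDb tables

_CATEGORY_TAGS = {
    "integrated": DatasetCategory.INTEGRATED,
    "whole_organism": DatasetCategory.WHOLE_ORGANISM,
    "tissue": DatasetCategory.TISSUE,
    "cell_line": DatasetCategory.CELL_LINE,
}


def write_paxdb(ds: AbundanceDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name: {ds.dataset_id}\n")
        if ds.category is DatasetCategory.INTEGRATED:
            fh.write("#integrated: true\n")
        fh.write(f"#organ: {ds.category.value}\n")
        fh.write("#string_id\tabundance_ppm\n")
        for protein in sorted(ds.abundances):
            fh.write(f"{protein}\t{ds.abundances[protein]:.6g}\n")


def read_paxdb(path: str | Path) -> AbundanceDataset:
    dataset_id = Path(path).stem
    category = DatasetCategory.WHOLE_ORGANISM
    abundances: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("#name:"):
                    dataset_id = line.split(":", 1)[1].strip()
                elif line.startswith("#integrated:"):
                    category = DatasetCategory.INTEGRATED
                elif line.startswith("#organ:") and category is not DatasetCategory.INTEGRATED:
                    tag = line.split(":", 1)[1].strip()
                    category = _CATEGORY_TAGS.get(tag, DatasetCategory.TISSUE)
                continue
            if not line.strip():
                continue
            protein, ppm = line.split("\t")[:2]
            abundances[protein] = float(ppm)
    return AbundanceDataset(dataset_id=dataset_id, abundances=abundances, category=category)


# ---------------------------------------------------- network / pair tables


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path):
    import networkx as nx

    net = nx.Graph()
    with open(path) as fh:
        fh.readline()
        for line in fh:
            u, v = line.rstrip("\n").split("\t")[:2]
            if u == v:
                logger.warning("self-loop %s-%s skipped", u, v)
                continue
            net.add_edge(u, v)
    return net


def write_halflife_table(table: HalfLifeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#dataset: {table.dataset_tag}\n#units: {table.units.value}\n")
        fh.write("protein\thalf_life\n")
        for p in sorted(table.values):
            fh.write(f"{p}\t{table.values[p]:.6g}\n")


def read_halflife_table(path: str | Path) -> HalfLifeTable:
    tag, units = "", HalfLifeUnits.RELATIVE
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#dataset:"):
                tag = line.split(":", 1)[1].strip()
            elif line.startswith("#units:"):
                units = HalfLifeUnits(line.split(":", 1)[1].strip())
            elif line.startswith(("#", "protein\t")) or not line.strip():
                continue
            else:
                p, t = line.split("\t")[:2]
                values[p] = float(t)
    return HalfLifeTable(values=values, units=units, dataset_tag=tag)


def write_coexpression(pairs: dict[frozenset, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tpearson_r\n")
        for key in sorted(pairs, key=lambda k: tuple(sorted(k))):
            a, b = sorted(key)
            fh.write(f"{a}\t{b}\t{pairs[key]:.4f}\n")


def read_coexpression(path: str | Path) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            a, b, r = line.rstrip("\n").split("\t")[:3]
            out[frozenset((a, b))] = float(r)
    return out


def write_semsim_pairs(pairs: dict[frozenset, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tsemsim\n")
        for key in sorted(pairs, key=lambda k: tuple(sorted(k))):
            a, b = sorted(key)
            fh.write(f"{a}\t{b}\t{pairs[key]:.6f}\n")


def read_semsim_pairs(path: str | Path) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            a, b, s = line.rstrip("\n").split("\t")[:3]
            out[frozenset((a, b))] = float(s)
    return out
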