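"""Synthetic input generation with planted, recoverable signal.

One call to :func:`generate` writes an internally consistent fixture set:
an N0-style orthogroup table, per-species DE tables, an outfmt-6 hit
table, a GO map plus toy OBO, species/hypotheses tables, an optional
peptide FASTA and newick tree, and truth tables for every planted signal.
Identical (config, seed) pairs produce byte-identical files.

Planting guarantees:

* *Expansions* -- for each planted hypothesis a block of OGs receives
  expanded_in counts of ``ceil(factor * max(compared_to counts)) + margin``;
  every non-planted OG is clamped so that no expanded_in species exceeds
  the compared_to maximum (factor <= 1), so calling at any factor above 1
  recovers exactly the planted set.
* *DEGs* -- adjusted p-values are drawn from a Uniform(0,1) null or a
  Beta(0.5, 20) signal mixture; signal genes are recorded in the truth
  table.
* *Neighborhoods* -- each planted-expanded OG gets a single-species
  "satellite" OG in a species absent from the host, with host<->satellite
  hits scored below within-OG hits, making the satellite the host's
  unique RBH neighbor.
* *GO terms* -- planted terms are attached to study-rate/background-rate
  fractions of study vs background OGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = ["PlantedExpansion", "PlantedTerm", "SimConfig", "generate", "truth_compare"]

AMINO = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PlantedExpansion:
    fraction: float
    expanded_in: tuple[str, ...]
    compared_to: tuple[str, ...]
    factor: float = 3.0
    margin: int = 1

    def __post_init__(self) -> None:
        self.expanded_in = tuple(self.expanded_in)
        self.compared_to = tuple(self.compared_to)
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if set(self.expanded_in) & set(self.compared_to):
            raise ValueError("expanded_in and compared_to overlap")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    @property
    def species(self) -> set[str]:
        return set(self.expanded_in) | set(self.compared_to)


@dataclass
class PlantedTerm:
    study_rate: float
    background_rate: float
    term: str | None = None  # auto-assigned when None

    def __post_init__(self) -> None:
        for r in (self.study_rate, self.background_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")


@dataclass
class SimConfig:
    """Full description of one synthetic fixture set."""

    species: dict[str, int]  # name -> ploidy
    n_ogs: int = 100
    mean_family_size: float = 2.0
    presence_prob: float = 0.9
    planted_expansions: list[PlantedExpansion] = field(default_factory=list)
    deg_rate_background: float = 0.02
    deg_rate_in_expanded: float = 0.5
    padj_na_rate: float = 0.0
    n_go_terms: int = 30
    planted_enriched_terms: list[PlantedTerm] = field(default_factory=list)
    mu_in: float = 300.0
    mu_out: float = 120.0
    sigma: float = 15.0
    max_count: int = 50
    n_fasta_genes: int = 10
    plant_satellites: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("need at least two species")
        if any(p < 1 for p in self.species.values()):
            raise ValueError("ploidy must be >= 1")
        if self.n_ogs < 1:
            raise ValueError("n_ogs must be >= 1")
        if self.mean_family_size < 1:
            raise ValueError("mean_family_size must be >= 1")
        for rate in (
            self.presence_prob,
            self.deg_rate_background,
            self.deg_rate_in_expanded,
            self.padj_na_rate,
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {rate} outside [0, 1]")
        if not self.mu_in > self.mu_out:
            raise ValueError("mu_in must exceed mu_out")
        n_planted = 0
        for pe in self.planted_expansions:
            unknown = pe.species - set(self.species)
            if unknown:
                raise ValueError(f"planted expansion names unknown species {sorted(unknown)}")
            n_planted += round(pe.fraction * self.n_ogs)
            # compared_to counts are drawn from {1, 2}
            peak = math.ceil(pe.factor * 2) + pe.margin
            if peak > self.max_count:
                raise ValueError(
                    f"impossible planting: factor {pe.factor} with margin "
                    f"{pe.margin} needs counts up to {peak} > max_count "
                    f"{self.max_count}"
                )
        if n_planted > self.n_ogs:
            raise ValueError("planted expansion fractions exceed the OG budget")

    @staticmethod
    def from_dict(d: dict) -> "SimConfig":
        d = dict(d)
        d["planted_expansions"] = [
            PlantedExpansion(**pe) for pe in d.get("planted_expansions", [])
        ]
        d["planted_enriched_terms"] = [
            PlantedTerm(**pt) for pt in d.get("planted_enriched_terms", [])
        ]
        return SimConfig(**d)

    @staticmethod
    def from_yaml(path: str | Path) -> "SimConfig":
        with Path(path).open() as fh:
            return SimConfig.from_dict(yaml.safe_load(fh))


def _fmt(x: float) -> str:
    return repr(float(x))


def generate(
    config: SimConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write the complete fixture set; returns a name -> path map."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species = list(config.species)
    n = config.n_ogs

    # --- planted blocks -------------------------------------------------
    blocks: list[list[int]] = []
    start = 0
    for pe in config.planted_expansions:
        size = round(pe.fraction * n)
        blocks.append(list(range(start, start + size)))
        start += size

    # --- per-OG per-species counts --------------------------------------
    counts = np.zeros((n, len(species)), dtype=int)
    sp_idx = {sp: j for j, sp in enumerate(species)}
    p_geom = 1.0 / config.mean_family_size
    for i in range(n):
        for j in range(len(species)):
            if rng.random() < config.presence_prob:
                counts[i, j] = min(int(rng.geometric(p_geom)), config.max_count)
    for pe, block in zip(config.planted_expansions, blocks):
        for i in block:
            for t in pe.compared_to:
                counts[i, sp_idx[t]] = int(rng.integers(1, 3))
            peak = max(counts[i, sp_idx[t]] for t in pe.compared_to)
            target = math.ceil(pe.factor * peak) + pe.margin
            for s in pe.expanded_in:
                counts[i, sp_idx[s]] = target
    # clamp every OG outside a hypothesis' block so it cannot be called
    # expanded for that hypothesis at any factor > 1
    for pe, block in zip(config.planted_expansions, blocks):
        inside = set(block)
        for i in range(n):
            if i in inside:
                continue
            cmax = max(counts[i, sp_idx[t]] for t in pe.compared_to)
            for s in pe.expanded_in:
                j = sp_idx[s]
                counts[i, j] = 0 if cmax == 0 else min(counts[i, j], cmax)

    # --- satellites for neighborhood truth ------------------------------
    satellites: list[tuple[int, str, str]] = []  # (host index, og_id, species)
    sat_counts: dict[str, dict[str, int]] = {}
    next_og = n
    truth_neighbors: list[tuple[str, str]] = []
    if config.plant_satellites:
        for pe, block in zip(config.planted_expansions, blocks):
            free = [sp for sp in species if sp not in pe.species]
            if not free:
                continue
            for i in block:
                sat_sp = free[i % len(free)]
                counts[i, sp_idx[sat_sp]] = 0
                sat_id = f"N0.HOG{next_og:07d}"
                next_og += 1
                satellites.append((i, sat_id, sat_sp))
                sat_counts[sat_id] = {sat_sp: int(rng.integers(1, 3))}

    # --- gene ids + orthogroup table ------------------------------------
    og_ids = [f"N0.HOG{i:07d}" for i in range(n)]
    genes: dict[str, dict[str, list[str]]] = {}
    for i, og in enumerate(og_ids):
        genes[og] = {
            sp: [f"{sp}_HOG{i:07d}_g{j + 1}" for j in range(counts[i, sp_idx[sp]])]
            for sp in species
        }
    for host_i, sat_id, sat_sp in satellites:
        genes[sat_id] = {sp: [] for sp in species}
        genes[sat_id][sat_sp] = [
            f"{sat_sp}_{sat_id.replace('N0.', '')}_g{j + 1}"
            for j in range(sat_counts[sat_id][sat_sp])
        ]
        truth_neighbors.append((og_ids[host_i], sat_id))
    all_og_ids = list(genes)

    paths: dict[str, Path] = {}

    def _register(name: str, filename: str) -> Path:
        paths[name] = out / filename
        return paths[name]

    with _register("orthogroups", "N0.tsv").open("w") as fh:
        fh.write("HOG\tOG\tGene Tree Parent Clade\t" + "\t".join(species) + "\n")
        for og in all_og_ids:
            cells = [", ".join(genes[og][sp]) for sp in species]
            fh.write(f"{og}\tOG{og[-7:]}\tn0\t" + "\t".join(cells) + "\n")

    # --- species table ---------------------------------------------------
    with _register("species", "species.tsv").open("w") as fh:
        fh.write("species\tploidy\tgo_annotation_path\n")
        for sp in species:
            fh.write(f"{sp}\t{config.species[sp]}\tgo_map.tsv\n")

    # --- hypotheses table ------------------------------------------------
    with _register("hypotheses", "hypotheses.tsv").open("w") as fh:
        fh.write(
            "hypothesis\tname\texpanded_in\tcompared_to\tNmin_expanded_in"
            "\tmin_expansion_factor\tmin_expansion_difference\n"
        )
        for idx, pe in enumerate(config.planted_expansions, start=1):
            fh.write(
                f"{idx}\thyp_{idx}\t{';'.join(pe.expanded_in)}\t"
                f"{';'.join(pe.compared_to)}\t{len(pe.expanded_in)}\t"
                f"{pe.factor}\t0\n"
            )

    # --- truth: expansions ----------------------------------------------
    with _register("truth_expansions", "truth_expansions.tsv").open("w") as fh:
        fh.write("og_id\thypothesis\tfactor\tmargin\n")
        for idx, (pe, block) in enumerate(
            zip(config.planted_expansions, blocks), start=1
        ):
            for i in block:
                fh.write(f"{og_ids[i]}\t{idx}\t{pe.factor}\t{pe.margin}\n")

    # --- DE tables -------------------------------------------------------
    expanded_gene_sets: dict[str, set[str]] = {sp: set() for sp in species}
    for pe, block in zip(config.planted_expansions, blocks):
        for i in block:
            for s in pe.expanded_in:
                expanded_gene_sets[s].update(genes[og_ids[i]][s])
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    paths["de_dir"] = de_dir
    truth_degs: list[tuple[str, str]] = []
    for sp in species:
        with (de_dir / f"{sp}.tsv").open("w") as fh:
            fh.write("gene_id\tlog2FoldChange\tpvalue\tpadj\n")
            for og in all_og_ids:
                for g in genes[og][sp]:
                    rate = (
                        config.deg_rate_in_expanded
                        if g in expanded_gene_sets[sp]
                        else config.deg_rate_background
                    )
                    if rng.random() < rate:
                        padj = float(rng.beta(0.5, 20.0))
                        lfc = float(rng.normal(0, 0.5) + rng.choice((-2.5, 2.5)))
                        truth_degs.append((sp, g))
                        fh.write(
                            f"{g}\t{_fmt(lfc)}\t{_fmt(padj * rng.random())}\t{_fmt(padj)}\n"
                        )
                    elif rng.random() < config.padj_na_rate:
                        fh.write(
                            f"{g}\t{_fmt(rng.normal(0, 1))}\t{_fmt(rng.random())}\tNA\n"
                        )
                    else:
                        padj = float(rng.random())
                        fh.write(
                            f"{g}\t{_fmt(rng.normal(0, 1))}\t{_fmt(padj * rng.random())}\t{_fmt(padj)}\n"
                        )
    with _register("truth_degs", "truth_degs.tsv").open("w") as fh:
        fh.write("species\tgene_id\n")
        for sp, g in truth_degs:
            fh.write(f"{sp}\t{g}\n")

    # --- hit table -------------------------------------------------------
    def _hit_row(q: str, s: str, bit: float) -> str:
        bit = max(25.0, bit)
        length = int(rng.integers(80, 400))
        pident = float(np.round(rng.uniform(60, 100), 1))
        mism = int(rng.integers(0, 30))
        gap = int(rng.integers(0, 5))
        ev = max(1e-180, 10.0 ** (-bit / 10.0))
        return (
            f"{q}\t{s}\t{pident}\t{length}\t{mism}\t{gap}\t1\t{length}\t1\t"
            f"{length}\t{ev:.3e}\t{bit:.1f}\n"
        )

    host_of_sat = {sat_id: og_ids[host_i] for host_i, sat_id, _ in satellites}
    with _register("hits", "hits.tsv").open("w") as fh:
        for og in all_og_ids:
            members = [(sp, g) for sp in species for g in genes[og][sp]]
            for sp_a, g_a in members:
                fh.write(_hit_row(g_a, g_a, 2 * config.mu_in))
                for sp_b, g_b in members:
                    if g_a != g_b and sp_a != sp_b:
                        fh.write(
                            _hit_row(g_a, g_b, float(rng.normal(config.mu_in, config.sigma)))
                        )
        for sat_id, host_id in host_of_sat.items():
            sat_members = [g for sp in species for g in genes[sat_id][sp]]
            host_members = [g for sp in species for g in genes[host_id][sp]]
            for g_a in host_members:
                for g_b in sat_members:
                    fh.write(
                        _hit_row(g_a, g_b, float(rng.normal(config.mu_out, config.sigma)))
                    )
                    fh.write(
                        _hit_row(g_b, g_a, float(rng.normal(config.mu_out, config.sigma)))
                    )
    with _register("truth_neighbors", "truth_neighbors.tsv").open("w") as fh:
        fh.write("focal_og\tneighbor_og\n")
        for host, sat in truth_neighbors:
            fh.write(f"{host}\t{sat}\n")

    # --- ontology + annotations -----------------------------------------
    roots = {
        "GO:0000001": ("biological_process", "biological_process"),
        "GO:0000002": ("molecular_function", "molecular_function"),
        "GO:0000003": ("cellular_component", "cellular_component"),
    }
    terms: dict[str, tuple[str, str, str | None]] = {
        t: (name, ns, None) for t, (name, ns) in roots.items()
    }
    bp_terms: list[str] = []
    for i in range(4, config.n_go_terms + 1):
        tid = f"GO:{i:07d}"
        parent_pool = ["GO:0000001"] + bp_terms
        parent = parent_pool[int(rng.integers(0, len(parent_pool)))]
        terms[tid] = (f"process_{i}", "biological_process", parent)
        bp_terms.append(tid)
    planted_term_ids: list[str] = []
    for j, pt in enumerate(config.planted_enriched_terms):
        tid = pt.term or f"GO:{config.n_go_terms + 1 + j:07d}"
        if tid not in terms:
            terms[tid] = (f"planted_process_{j + 1}", "biological_process", "GO:0000001")
        planted_term_ids.append(tid)

    with _register("obo", "ontology.obo").open("w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for tid, (name, ns, parent) in terms.items():
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: {ns}\n")
            if parent is not None:
                fh.write(f"is_a: {parent} ! {terms[parent][0]}\n")

    # study set for planted terms: the first planted-expansion block, or
    # the first tenth of OGs when no expansion is planted
    if blocks and blocks[0]:
        study_idx = blocks[0]
    else:
        study_idx = list(range(max(1, n // 10)))
    study_ogs = {og_ids[i] for i in study_idx}

    noise_pool = bp_terms or ["GO:0000001"]
    annotations: dict[str, list[str]] = {}
    for og in all_og_ids:
        for sp in species:
            for g in genes[og][sp]:
                k = int(rng.integers(1, 4))
                picks = sorted(
                    {noise_pool[int(rng.integers(0, len(noise_pool)))] for _ in range(k)}
                )
                annotations[g] = picks
    truth_term_rows: list[tuple[str, int, int]] = []
    for pt, tid in zip(config.planted_enriched_terms, planted_term_ids):
        n_study = n_bg = 0
        for og in all_og_ids:
            rate = pt.study_rate if og in study_ogs else pt.background_rate
            if rng.random() < rate:
                member_genes = [g for sp in species for g in genes[og][sp]]
                if not member_genes:
                    continue
                g = member_genes[int(rng.integers(0, len(member_genes)))]
                annotations[g].append(tid)
                if og in study_ogs:
                    n_study += 1
                else:
                    n_bg += 1
        truth_term_rows.append((tid, n_study, n_bg))

    with _register("go_map", "go_map.tsv").open("w") as fh:
        for g in sorted(annotations):
            fh.write(f"{g}\t{','.join(sorted(set(annotations[g])))}\n")
    with _register("truth_terms", "truth_terms.tsv").open("w") as fh:
        fh.write("term\tn_study_annotated\tn_background_annotated\n")
        for tid, ns_, nb_ in truth_term_rows:
            fh.write(f"{tid}\t{ns_}\t{nb_}\n")
    with _register("truth_go_study", "truth_go_study.tsv").open("w") as fh:
        fh.write("og_id\n")
        for og in sorted(study_ogs):
            fh.write(f"{og}\n")

    # --- peptide FASTA (isoform-filter fodder) ---------------------------
    first_sp = species[0]
    fasta_genes = [
        g for og in all_og_ids for g in genes[og][first_sp]
    ][: config.n_fasta_genes]
    with _register("fasta", "peptides.fa").open("w") as fh:
        for g in fasta_genes:
            for iso in range(1, int(rng.integers(1, 4)) + 1):
                length = int(rng.integers(50, 200))
                seq = "M" + "".join(
                    AMINO[int(rng.integers(0, len(AMINO)))] for _ in range(length - 1)
                )
                fh.write(f">{g}.{iso}\n{seq}\n")

    # --- species tree (opaque pass-through) ------------------------------
    tree = species[0]
    for sp in species[1:]:
        tree = f"({tree},{sp})"
    _register("tree", "tree.nwk").write_text(tree + ";\n")

    return paths


def truth_compare(
    called: Iterable[str], truth: Iterable[str]
) -> tuple[float, float]:
    """Precision and recall of a called OG set against a truth set.

    Empty ``called`` yields precision 1.0 (no false positives); empty
    ``truth`` yields recall 1.0.
    """
    called_set, truth_set = set(called), set(truth)
    tp = len(called_set & truth_set)
    precision = tp / len(called_set) if called_set else 1.0
    recall = tp / len(truth_set) if truth_set else 1.0
    return precision, recall
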