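"""Readers and writers for every external format, plus the results bundle.

Supported inputs: Orthofinder-style hierarchical orthogroup tables
(``N0.tsv`` dialect), per-species differential-expression tables, 12-column
tabular protein hit tables (BLAST/DIAMOND ``-outfmt 6``), GO annotation
maps, species tables, hypotheses tables and peptide FASTA files.

The results bundle is an open directory of TSV files plus a JSON manifest
with per-file checksums; a subsetted bundle validates against the same
schema as a full one.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .expansion import Hypothesis

__all__ = [
    "OrthoGroupTable",
    "SpeciesProfile",
    "DERecord",
    "HitRecord",
    "ResultsBundle",
    "read_orthogroups",
    "read_species_table",
    "read_hypotheses",
    "read_de_table",
    "read_hits",
    "read_go_map",
    "filter_longest_isoform",
    "write_bundle",
    "read_bundle",
    "subset_bundle",
]

HIT_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

#: Files-path sentinels accepted in species tables instead of a GO map path.
GO_PATH_SENTINELS = frozenset({"", "-", "NA", "AHRD"})


@dataclass
class OrthoGroupTable:
    """Central membership structure: OG id -> species -> ordered gene list.

    Every species of ``species_order`` is present as a key in every row;
    empty cells are empty lists, never missing keys.
    """

    rows: dict[str, dict[str, list[str]]]
    species_order: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og_id, row in self.rows.items():
            for sp in self.species_order:
                row.setdefault(sp, [])
            for sp, genes in row.items():
                if sp not in self.species_order:
                    raise ValueError(
                        f"OG {og_id}: species {sp!r} not in species_order"
                    )
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene id {g!r} appears in both {seen[g]} and {og_id}"
                        )
                    seen[g] = og_id

    @property
    def og_ids(self) -> list[str]:
        return list(self.rows)

    def counts(self, og_id: str) -> dict[str, int]:
        return {sp: len(g) for sp, g in self.rows[og_id].items()}

    def genes_of(self, og_id: str) -> list[str]:
        row = self.rows[og_id]
        return [g for sp in self.species_order for g in row[sp]]

    def gene_to_og(self) -> dict[str, str]:
        return {
            g: og_id for og_id, row in self.rows.items() for gs in row.values() for g in gs
        }

    def gene_to_species(self) -> dict[str, str]:
        return {
            g: sp for row in self.rows.values() for sp, gs in row.items() for g in gs
        }

    def subset(self, og_ids: Iterable[str]) -> "OrthoGroupTable":
        keep = set(og_ids)
        unknown = keep - set(self.rows)
        if unknown:
            raise KeyError(f"unknown OG ids: {sorted(unknown)}")
        return OrthoGroupTable(
            rows={og: {sp: list(v) for sp, v in row.items()}
                  for og, row in self.rows.items() if og in keep},
            species_order=list(self.species_order),
        )


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    ploidy: int
    go_annotation_path: str | None = None

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError(f"species {self.name!r}: ploidy must be >= 1")


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression result table."""

    gene_id: str
    species: str
    log2fc: float
    pvalue: float | None
    padj: float | None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        for name, v in (("pvalue", self.pvalue), ("padj", self.padj)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.gene_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class HitRecord:
    """One 12-column tabular hit (outfmt-6 dialect)."""

    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_orthogroups(path: str | Path) -> OrthoGroupTable:
    """Parse an Orthofinder ``N0.tsv``-style hierarchical orthogroup table.

    Header: ``HOG``, ``OG``, ``Gene Tree Parent Clade`` then one column per
    species; gene lists are comma-separated.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 4:
            raise ValueError(
                f"{path}: expected >= 4 columns (HOG, OG, clade, species...), "
                f"got {len(header)}"
            )
        species = header[3:]
        rows: dict[str, dict[str, list[str]]] = {}
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: ragged row with {len(rec)} fields, "
                    f"expected {len(header)}"
                )
            og_id = rec[0]
            if og_id in rows:
                raise ValueError(f"{path}:{lineno}: duplicate OG id {og_id!r}")
            rows[og_id] = {
                sp: [g.strip() for g in cell.split(",") if g.strip()]
                for sp, cell in zip(species, rec[3:])
            }
    return OrthoGroupTable(rows=rows, species_order=species)


def read_species_table(path: str | Path) -> list[SpeciesProfile]:
    """Read a species table: columns ``species``, ``ploidy`` and optionally
    a per-species GO annotation path (sentinels like ``AHRD`` become None)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"species", "ploidy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing columns {sorted(missing)}; found {list(df.columns)}"
        )
    profiles = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = row["species"].strip()
        if name in seen:
            raise ValueError(f"{path}: duplicate species {name!r}")
        seen.add(name)
        go_path = row.get("go_annotation_path", "")
        profiles.append(
            SpeciesProfile(
                name=name,
                ploidy=int(row["ploidy"]),
                go_annotation_path=None if go_path in GO_PATH_SENTINELS else go_path,
            )
        )
    return profiles


def read_hypotheses(
    path: str | Path,
    species: Sequence[str] | None = None,
) -> list[Hypothesis]:
    """Read the hypotheses table.

    Columns: ``hypothesis`` (integer index), ``name``, ``expanded_in``,
    ``compared_to`` (semicolon-separated species lists),
    ``Nmin_expanded_in``, ``min_expansion_factor``,
    ``min_expansion_difference``. An optional ``ploidy_normalize`` column
    (true/false) is honoured. When ``species`` is supplied, unknown species
    names are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "hypothesis",
        "name",
        "expanded_in",
        "compared_to",
        "Nmin_expanded_in",
        "min_expansion_factor",
        "min_expansion_difference",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; found {list(df.columns)}"
        )
    known = set(species) if species is not None else None
    hypotheses = []
    for _, row in df.iterrows():
        expanded_in = frozenset(
            s.strip() for s in row["expanded_in"].split(";") if s.strip()
        )
        compared_to = frozenset(
            s.strip() for s in row["compared_to"].split(";") if s.strip()
        )
        if known is not None:
            unknown = sorted((expanded_in | compared_to) - known)
            if unknown:
                raise ValueError(
                    f"{path}: hypothesis {row['hypothesis']}: unknown species "
                    f"{unknown}"
                )
        try:
            hyp = Hypothesis(
                index=int(row["hypothesis"]),
                name=row["name"],
                expanded_in=expanded_in,
                compared_to=compared_to,
                nmin_expanded_in=int(row["Nmin_expanded_in"]),
                min_expansion_factor=float(row["min_expansion_factor"]),
                min_expansion_difference=int(row["min_expansion_difference"]),
                ploidy_normalize=str(row.get("ploidy_normalize", "false")).lower()
                in ("true", "1", "yes"),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
        hypotheses.append(hyp)
    return hypotheses


# Synonyms accepted for the three required DE statistic columns and the id.
DE_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "gene_id": ("gene_id", "gene", "id", "row", "rowname", "transcript_id"),
    "log2fc": ("log2FoldChange", "log2fc", "lfc", "logFC"),
    "pvalue": ("pvalue", "pval", "p_value", "PValue"),
    "padj": ("padj", "p_adj", "qvalue", "fdr", "FDR", "adj.P.Val"),
}


def read_de_table(
    path: str | Path,
    species: str,
    column_map: Mapping[str, str] | None = None,
) -> list[DERecord]:
    """Read one per-species differential-expression result table.

    ``NA``/empty p-values are preserved as missing, never coerced to 0 or 1.
    Extra columns are ignored. ``column_map`` overrides the default synonym
    resolution, e.g. ``{"padj": "my_fdr_column"}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    resolved: dict[str, str] = {}
    for field_name, synonyms in DE_COLUMN_SYNONYMS.items():
        if column_map and field_name in column_map:
            if column_map[field_name] not in df.columns:
                raise ValueError(
                    f"{path}: mapped column {column_map[field_name]!r} for "
                    f"{field_name!r} not found; headers: {list(df.columns)}"
                )
            resolved[field_name] = column_map[field_name]
            continue
        for syn in synonyms:
            if syn in df.columns:
                resolved[field_name] = syn
                break
        else:
            if field_name == "gene_id" and len(df.columns) > 0:
                # DESeq2 exports often carry the id as an unnamed first column
                resolved[field_name] = df.columns[0]
            else:
                raise ValueError(
                    f"{path}: no column for {field_name!r} (tried "
                    f"{list(synonyms)}); headers found: {list(df.columns)}"
                )

    def _num(v: str) -> float | None:
        v = v.strip()
        if v in ("", "NA", "NaN", "nan"):
            return None
        return float(v)

    records = []
    for _, row in df.iterrows():
        lfc = _num(row[resolved["log2fc"]])
        records.append(
            DERecord(
                gene_id=row[resolved["gene_id"]].strip(),
                species=species,
                log2fc=0.0 if lfc is None else lfc,
                pvalue=_num(row[resolved["pvalue"]]),
                padj=_num(row[resolved["padj"]]),
            )
        )
    return records


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular hit file (BLAST/DIAMOND ``-outfmt 6``)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=HIT_COLUMNS,
        dtype={
            "query": str,
            "subject": str,
            "pident": float,
            "length": int,
            "mismatch": int,
            "gapopen": int,
            "qstart": int,
            "qend": int,
            "sstart": int,
            "send": int,
            "evalue": float,
            "bitscore": float,
        },
    )
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {df.shape[1]}")
    if (df["bitscore"] < 0).any():
        raise ValueError(f"{path}: negative bitscore")
    return df


def hits_to_records(hits: pd.DataFrame) -> list[HitRecord]:
    return [HitRecord(**row) for row in hits.to_dict("records")]


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO terms map (TSV: gene_id, comma-separated GO ids)."""
    out: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0].strip()
            if not gene:
                raise ValueError(f"{path}:{lineno}: empty gene id")
            terms = set()
            if len(parts) > 1:
                terms = {t.strip() for t in parts[1].split(",") if t.strip()}
            out.setdefault(gene, set()).update(terms)
    return out


# ---------------------------------------------------------------------------
# longest-isoform filtering
# ---------------------------------------------------------------------------

#: Default rule: strip a trailing ``.1`` / ``_T01`` / ``.t3`` style suffix.
DEFAULT_ISOFORM_REGEX = r"^(?P<gene>.+?)(?:\.\d+|[._][Tt]\d+)?$"


def filter_longest_isoform(
    fasta_in: str | Path,
    fasta_out: str | Path,
    mapping_out: str | Path,
    gene_id_regex: str = DEFAULT_ISOFORM_REGEX,
) -> dict[str, str]:
    """Keep only the longest isoform per gene, shortening headers to the
    bare gene id.

    ``gene_id_regex`` must expose a ``gene`` named group mapping an isoform
    id to its gene id. Ties on length keep the lexicographically smallest
    isoform id. A two-column isoform -> gene mapping table is written to
    ``mapping_out``. Returns the isoform -> gene mapping of kept records.
    """
    pattern = re.compile(gene_id_regex)
    best: dict[str, tuple[int, str, object]] = {}
    mapping: list[tuple[str, str]] = []
    seen_isoforms: set[str] = set()
    for rec in SeqIO.parse(str(fasta_in), "fasta"):
        if rec.id in seen_isoforms:
            raise ValueError(f"{fasta_in}: duplicate record id {rec.id!r}")
        seen_isoforms.add(rec.id)
        m = pattern.match(rec.id)
        if m is None or not m.group("gene"):
            raise ValueError(
                f"{fasta_in}: id {rec.id!r} does not match gene_id_regex"
            )
        gene = m.group("gene")
        mapping.append((rec.id, gene))
        cur = best.get(gene)
        cand = (-len(rec.seq), rec.id)
        if cur is None or cand < (cur[0], cur[1]):
            best[gene] = (-len(rec.seq), rec.id, rec)
    kept: dict[str, str] = {}
    with Path(fasta_out).open("w") as out:
        for gene in sorted(best):
            _, iso_id, rec = best[gene]
            kept[iso_id] = gene
            out.write(f">{gene}\n{str(rec.seq)}\n")
    with Path(mapping_out).open("w") as out:
        out.write("isoform_id\tgene_id\n")
        for iso, gene in mapping:
            out.write(f"{iso}\t{gene}\n")
    return kept


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------

#: Table columns recognised when subsetting by OG.
_OG_COLUMNS = ("og_id", "focal_og")


@dataclass
class ResultsBundle:
    """An open directory-of-TSVs results container.

    ``tables`` maps member name -> DataFrame (written as ``<name>.tsv``);
    ``texts`` maps member name -> opaque text (e.g. a newick species tree,
    written as ``<name>.txt``). The manifest records tool/schema versions,
    the config hash, the seed and per-file checksums.
    """

    manifest: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    texts: dict[str, str] = field(default_factory=dict)

    def og_ids(self) -> set[str]:
        if "og_genes" in self.tables:
            return set(self.tables["og_genes"]["og_id"])
        ids: set[str] = set()
        for df in self.tables.values():
            for col in _OG_COLUMNS:
                if col in df.columns:
                    ids.update(df[col])
        return ids


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> dict:
    """Serialise the bundle; returns the manifest written to
    ``manifest.json`` (with per-file sha256 checksums)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}
    for name, df in bundle.tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        files[name] = {"path": p.name, "kind": "table", "sha256": _sha256(p),
                       "rows": int(df.shape[0])}
    for name, text in bundle.texts.items():
        p = out / f"{name}.txt"
        p.write_text(text)
        files[name] = {"path": p.name, "kind": "text", "sha256": _sha256(p)}
    manifest = dict(bundle.manifest)
    from . import SCHEMA_VERSION, __version__

    manifest.setdefault("tool", "ogxpand")
    manifest.setdefault("version", __version__)
    manifest.setdefault("schema_version", SCHEMA_VERSION)
    manifest["created"] = datetime.now(timezone.utc).isoformat()
    manifest["files"] = files
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle.manifest = manifest
    return manifest


def read_bundle(in_dir: str | Path, verify: bool = True) -> ResultsBundle:
    """Load a bundle directory written by :func:`write_bundle`."""
    indir = Path(in_dir)
    manifest_path = indir / "manifest.json"
    if not manifest_path.is_file():
        raise FileNotFoundError(f"{indir}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    tables: dict[str, pd.DataFrame] = {}
    texts: dict[str, str] = {}
    for name, meta in manifest.get("files", {}).items():
        p = indir / meta["path"]
        if not p.is_file():
            raise FileNotFoundError(f"{indir}: manifest names missing file {p.name}")
        if verify and _sha256(p) != meta["sha256"]:
            raise ValueError(f"{indir}: checksum mismatch for {p.name}")
        if meta["kind"] == "table":
            tables[name] = pd.read_csv(p, sep="\t")
        else:
            texts[name] = p.read_text()
    return ResultsBundle(manifest=manifest, tables=tables, texts=texts)


def subset_bundle(bundle: ResultsBundle, og_ids: Iterable[str]) -> ResultsBundle:
    """Restrict a bundle to the given OGs (the bookmark-export analog).

    Tables carrying an OG id column keep only rows for the kept OGs;
    tables carrying a ``gene_id`` column keep only genes of the kept OGs
    (requires the ``og_genes`` membership table); all other tables are
    copied whole. Re-loading a subset yields identical values for kept
    OGs as the full bundle.
    """
    keep = set(og_ids)
    known = bundle.og_ids()
    unknown = sorted(keep - known)
    if unknown:
        raise KeyError(f"unknown OG ids: {unknown}")
    kept_genes: set[str] | None = None
    if "og_genes" in bundle.tables:
        og_genes = bundle.tables["og_genes"]
        kept_genes = set(og_genes.loc[og_genes["og_id"].isin(keep), "gene_id"])
    tables: dict[str, pd.DataFrame] = {}
    for name, df in bundle.tables.items():
        og_col = next((c for c in _OG_COLUMNS if c in df.columns), None)
        if og_col is not None:
            tables[name] = df[df[og_col].isin(keep)].reset_index(drop=True)
        elif "gene_id" in df.columns and kept_genes is not None:
            tables[name] = df[df["gene_id"].isin(kept_genes)].reset_index(drop=True)
        else:
            tables[name] = df.copy()
    manifest = {
        k: v for k, v in bundle.manifest.items() if k not in ("files", "created")
    }
    manifest["subset_of"] = bundle.manifest.get("config_hash")
    manifest["subset_og_count"] = len(keep)
    return ResultsBundle(manifest=manifest, tables=tables, texts=dict(bundle.texts))
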