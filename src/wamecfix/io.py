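"""Typed data model and validated IO for whole-assemblage metatranscriptome tables.

The pipeline works on four kinds of input:

* a **unigene catalog** — one row per assembled transcript (unigene) with its
  length, ranked taxonomy and functional annotations (KEGG KO and Pfam IDs);
* a **raw count matrix** — unigenes x sequencing libraries;
* a **sample table** — the library -> (station, layer, size fraction,
  replicate) design plus per-litre RNA yield and environmental covariates;
* a **pathway set** — named gene sets (KO/Pfam ID lists) with functional
  roles (Calvin-cycle marker, the five non-Calvin carbon-fixation pathways,
  endocytosis and photosynthesis core genes, microbial rhodopsin).

All tables are tab-separated UTF-8 text with a mandatory header and "." as
the decimal separator.  Pathway sets and the phylum -> supergroup mapping are
JSON.  In memory everything is pandas; the thin dataclass wrappers exist to
carry validation and schema knowledge, not to hide the DataFrame.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "INPUT_RANKS",
    "ENV_VARS",
    "LAYERS",
    "FRACTIONS",
    "UNCLASSIFIED",
    "SchemaError",
    "ReferentialError",
    "ValidationError",
    "UnigeneCatalog",
    "SampleTable",
    "Pathway",
    "PathwaySet",
    "read_catalog",
    "write_catalog",
    "read_samples",
    "write_samples",
    "read_counts",
    "write_matrix",
    "read_matrix",
    "load_default_pathways",
    "load_supergroup_map",
]

#: Full in-memory rank schema.  ``supergroup`` is a derived rank: it is
#: computed from ``phylum`` through an editable mapping table because it is
#: not a standard taxonomic rank (it groups e.g. the non-diatom stramenopile
#: phyla under one "O_Stramenopiles" label).
RANKS = ("domain", "supergroup", "phylum", "class", "order", "genus", "species")

#: Ranks carried by the semicolon-delimited lineage string of the catalog
#: file, in order.  Blank or missing positions become "unclassified".
INPUT_RANKS = ("domain", "phylum", "class", "order", "genus", "species")

ENV_VARS = ("temperature", "salinity", "depth", "no2_no3", "po4", "sio3", "par")
LAYERS = ("SUR", "DCM", "BOT")
FRACTIONS = ("small", "large")
UNCLASSIFIED = "unclassified"

_KO_RE = re.compile(r"^K\d{5}$")
_PFAM_RE = re.compile(r"^PF\d{5}$")

ROLES = (
    "ccf_marker",
    "ncf_pathway",
    "endocytosis_core",
    "photosynthesis_core",
    "rhodopsin",
)


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ReferentialError(ValueError):
    """An identifier does not resolve against the catalog or sample table."""


class ValidationError(ValueError):
    """A value violates a declared invariant."""


def _require_columns(frame: pd.DataFrame, required: Iterable[str], what: str) -> None:
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"{what}: missing required column '{col}'")


def _valid_gene_id(gene_id: str) -> bool:
    return bool(_KO_RE.match(gene_id) or _PFAM_RE.match(gene_id))


def _parse_id_set(cell: object, pattern: re.Pattern, what: str, row_id: str) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    ids = [tok.strip() for tok in str(cell).split(",") if tok.strip()]
    for tok in ids:
        if not pattern.match(tok):
            raise ValidationError(
                f"unigene '{row_id}': malformed {what} identifier '{tok}'"
            )
    return frozenset(ids)


def parse_lineage(lineage: object) -> dict:
    """Split a semicolon-delimited lineage string into the six input ranks.

    Blank positions and truncated strings are stored as ``unclassified``:
    ``"Bacteria;Proteobacteria;;Alteromonadales"`` yields class
    ``unclassified`` and order ``Alteromonadales``.
    """
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        parts: list[str] = []
    else:
        parts = [p.strip() for p in str(lineage).split(";")]
    if len(parts) > len(INPUT_RANKS):
        raise SchemaError(
            f"lineage string has {len(parts)} fields, at most {len(INPUT_RANKS)} allowed: "
            f"'{lineage}'"
        )
    parts = parts + [""] * (len(INPUT_RANKS) - len(parts))
    return {rank: (p if p else UNCLASSIFIED) for rank, p in zip(INPUT_RANKS, parts)}


def format_lineage(row: Mapping[str, str]) -> str:
    return ";".join(str(row[r]) for r in INPUT_RANKS)


@dataclass
class UnigeneCatalog:
    """Per-unigene length, ranked taxonomy and functional annotations.

    ``frame`` is indexed by unique ``unigene_id`` and carries ``length_bp``
    (int), the seven rank columns of :data:`RANKS`, and two frozenset columns
    ``ko_ids`` and ``pfam_ids``.  A unigene without any annotation is kept:
    it still contributes to per-library totals during normalization.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise ValidationError(f"duplicate unigene_id '{dup}'")
        for col in ("length_bp", "ko_ids", "pfam_ids", *RANKS):
            if col not in f.columns:
                raise SchemaError(f"catalog frame: missing column '{col}'")
        if (f["length_bp"] < 1).any():
            bad = f.index[f["length_bp"] < 1][0]
            raise ValidationError(f"unigene '{bad}': length_bp must be >= 1")
        for rank in RANKS:
            col = f[rank]
            if col.isna().any() or (col.astype(str).str.len() == 0).any():
                raise ValidationError(f"rank '{rank}' contains empty values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> pd.Index:
        return self.frame.index

    def lineage_at(self, rank: str) -> pd.Series:
        """Lineage label of every unigene at ``rank`` (one of :data:`RANKS`)."""
        if rank not in RANKS:
            raise ValidationError(f"unknown taxonomy rank '{rank}'; expected one of {RANKS}")
        return self.frame[rank]

    def genes_with(self, gene_ids: Iterable[str]) -> pd.Index:
        """Unigenes annotated to at least one of the given KO/Pfam IDs."""
        wanted = frozenset(gene_ids)
        kos = frozenset(g for g in wanted if g.startswith("K"))
        pfams = wanted - kos
        mask = np.zeros(len(self.frame), dtype=bool)
        if kos:
            mask |= np.fromiter(
                (bool(s & kos) for s in self.frame["ko_ids"]), dtype=bool, count=len(self.frame)
            )
        if pfams:
            mask |= np.fromiter(
                (bool(s & pfams) for s in self.frame["pfam_ids"]),
                dtype=bool,
                count=len(self.frame),
            )
        return self.frame.index[mask]


@dataclass
class SampleTable:
    """Library -> condition design with RNA yields and environmental data.

    Indexed by unique ``library_id``; columns ``station``, ``layer``
    (SUR/DCM/BOT), ``size_fraction`` (small = 0.2-3 um, large = 3-200 um),
    ``replicate`` (int), ``rna_yield_per_L`` (mass of total RNA extracted per
    litre of seawater; the unit cancels in the size-fraction calibration and
    only has to be consistent within a condition) and the environmental
    covariates of :data:`ENV_VARS` (any may be missing/NaN).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        f = self.frame
        _require_columns(f, ("station", "layer", "size_fraction", "replicate"), "sample table")
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise ValidationError(f"duplicate library_id '{dup}'")
        bad_layer = set(f["layer"]) - set(LAYERS)
        if bad_layer:
            raise ValidationError(f"unknown layer value(s) {sorted(bad_layer)}; expected {LAYERS}")
        bad_frac = set(f["size_fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ValidationError(
                f"unknown size_fraction value(s) {sorted(bad_frac)}; expected {FRACTIONS}"
            )
        key = f[["station", "layer", "size_fraction", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                "duplicate design cell (station, layer, size_fraction, replicate) = "
                f"{tuple(dup)}"
            )
        for var in ENV_VARS:
            if var in f.columns:
                vals = pd.to_numeric(f[var], errors="coerce")
                present = f[var].notna()
                if (~np.isfinite(vals[present])).any():
                    raise ValidationError(f"environment variable '{var}' has non-finite values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> pd.Index:
        return self.frame.index

    def condition_labels(self, include_fraction: bool = False) -> pd.Series:
        """Condition label per library: ``station_layer`` (water mass), or
        ``station_layer_fraction`` when the two size fractions are analysed
        as separate condition sets."""
        f = self.frame
        lab = f["station"].astype(str) + "_" + f["layer"].astype(str)
        if include_fraction:
            lab = lab + "_" + f["size_fraction"].astype(str)
        return lab

    def subset(self, size_fraction: str | None = None) -> "SampleTable":
        f = self.frame
        if size_fraction is not None:
            f = f[f["size_fraction"] == size_fraction]
        return SampleTable(f.copy())


@dataclass(frozen=True)
class Pathway:
    name: str
    role: str
    gene_ids: tuple

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"pathway '{self.name}': unknown role '{self.role}'")
        if not self.gene_ids:
            raise ValidationError(f"pathway '{self.name}': empty gene list")
        for g in self.gene_ids:
            if not _valid_gene_id(g):
                raise ValidationError(
                    f"pathway '{self.name}': malformed gene identifier '{g}' "
                    "(expected K##### or PF#####)"
                )


@dataclass
class PathwaySet:
    """Named KO/Pfam gene sets with functional roles.

    The packaged default carries the RuBisCO Calvin-cycle markers (K01601,
    K01602), the five non-Calvin carbon-fixation pathways (reductive citric
    acid cycle, Wood-Ljungdahl, 3-hydroxypropionate bicycle,
    hydroxypropionate-hydroxybutyrate cycle, dicarboxylate-hydroxybutyrate
    cycle), core photosynthesis and endocytosis gene sets, and the microbial
    rhodopsin domain PF01036.  Every list is overridable from a user JSON
    file of the same schema.
    """

    pathways: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, pw in self.pathways.items():
            if name != pw.name:
                raise ValidationError(f"pathway key '{name}' != pathway name '{pw.name}'")

    def __getitem__(self, name: str) -> Pathway:
        return self.pathways[name]

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def by_role(self, role: str) -> list:
        return [pw for pw in self.pathways.values() if pw.role == role]

    def role_genes(self, role: str) -> tuple:
        """Deduplicated union of gene IDs across all pathways of ``role``,
        in first-seen order."""
        seen: dict = {}
        for pw in self.by_role(role):
            for g in pw.gene_ids:
                seen.setdefault(g, None)
        return tuple(seen)

    @property
    def ncf_union(self) -> tuple:
        return self.role_genes("ncf_pathway")

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwaySet":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PathwaySet":
        pathways = {}
        for name, entry in raw.items():
            try:
                pw = Pathway(name=name, role=entry["role"], gene_ids=tuple(entry["genes"]))
            except KeyError as exc:
                raise SchemaError(f"pathway '{name}': missing field {exc}") from exc
            pathways[name] = pw
        return cls(pathways)

    def to_dict(self) -> dict:
        return {
            name: {"role": pw.role, "genes": list(pw.gene_ids)}
            for name, pw in self.pathways.items()
        }


def _resource_path(name: str):
    return _importlib_resources.files("wamecfix").joinpath("resources", name)


def load_default_pathways(override: str | Path | None = None) -> PathwaySet:
    """Load the packaged pathway definitions, or a user override file.

    The default configuration carries exactly five pathways with role
    ``ncf_pathway``; this is asserted at load time.
    """
    if override is not None:
        return PathwaySet.from_json(override)
    with _importlib_resources.as_file(_resource_path("default_pathways.json")) as p:
        ps = PathwaySet.from_json(p)
    n_ncf = len(ps.by_role("ncf_pathway"))
    if n_ncf != 5:
        raise ValidationError(f"default pathway set must define 5 NCF pathways, found {n_ncf}")
    return ps


def load_supergroup_map(path: str | Path | None = None) -> dict:
    """Phylum -> supergroup mapping; phyla absent from the map keep their own
    name as supergroup label."""
    if path is None:
        with _importlib_resources.as_file(_resource_path("default_supergroups.json")) as p:
            path = p
            with open(path, encoding="utf-8") as fh:
                return dict(json.load(fh))
    with open(path, encoding="utf-8") as fh:
        return dict(json.load(fh))


# ---------------------------------------------------------------------------
# readers / writers


def _fasta_lengths(path: str | Path) -> dict:
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_catalog(
    path: str | Path,
    supergroup_map: Mapping[str, str] | None = None,
    fasta: str | Path | None = None,
) -> UnigeneCatalog:
    """Read a tab-separated unigene catalog.

    Required columns: ``unigene_id``, ``length_bp`` (may instead be derived
    from a FASTA of unigene sequences via ``fasta``), ``lineage``
    (semicolon-delimited ranks), ``ko_ids`` and ``pfam_ids``
    (comma-delimited, may be blank).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    required = ["unigene_id", "lineage", "ko_ids", "pfam_ids"]
    if fasta is None:
        required.append("length_bp")
    _require_columns(frame, required, "catalog")
    if frame["unigene_id"].duplicated().any():
        dup = frame["unigene_id"][frame["unigene_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate unigene_id '{dup}'")
    frame = frame.set_index("unigene_id")

    if "length_bp" in frame.columns:
        lengths = pd.to_numeric(frame["length_bp"], errors="coerce")
        if lengths.isna().any():
            bad = frame.index[lengths.isna()][0]
            raise ValidationError(f"unigene '{bad}': length_bp is not an integer")
    else:
        lut = _fasta_lengths(fasta)
        missing = [u for u in frame.index if u not in lut]
        if missing:
            raise ReferentialError(f"unigene '{missing[0]}' absent from FASTA '{fasta}'")
        lengths = pd.Series([lut[u] for u in frame.index], index=frame.index, dtype=float)
    if (lengths < 1).any():
        bad = frame.index[lengths < 1][0]
        raise ValidationError(f"unigene '{bad}': length_bp must be >= 1")

    lineages = pd.DataFrame(
        [parse_lineage(v) for v in frame["lineage"]], index=frame.index
    )
    sg_map = dict(supergroup_map) if supergroup_map is not None else load_supergroup_map()
    supergroup = lineages["phylum"].map(lambda p: sg_map.get(p, p))

    out = pd.DataFrame(index=frame.index)
    out["length_bp"] = lengths.astype(int)
    out["domain"] = lineages["domain"]
    out["supergroup"] = supergroup
    for rank in INPUT_RANKS[1:]:
        out[rank] = lineages[rank]
    out["ko_ids"] = [
        _parse_id_set(v, _KO_RE, "KO", u) for u, v in frame["ko_ids"].items()
    ]
    out["pfam_ids"] = [
        _parse_id_set(v, _PFAM_RE, "Pfam", u) for u, v in frame["pfam_ids"].items()
    ]
    return UnigeneCatalog(out)


def write_catalog(catalog: UnigeneCatalog, path: str | Path) -> None:
    f = catalog.frame
    out = pd.DataFrame(index=f.index)
    out.index.name = "unigene_id"
    out["length_bp"] = f["length_bp"]
    out["lineage"] = [format_lineage(row) for _, row in f[list(INPUT_RANKS)].iterrows()]
    out["ko_ids"] = [",".join(sorted(s)) for s in f["ko_ids"]]
    out["pfam_ids"] = [",".join(sorted(s)) for s in f["pfam_ids"]]
    out.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", dtype={"library_id": str, "station": str})
    _require_columns(
        frame, ("library_id", "station", "layer", "size_fraction", "replicate"), "sample table"
    )
    if frame["library_id"].duplicated().any():
        dup = frame["library_id"][frame["library_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate library_id '{dup}'")
    frame = frame.set_index("library_id")
    frame["replicate"] = frame["replicate"].astype(int)
    if "rna_yield_per_L" in frame.columns:
        frame["rna_yield_per_L"] = pd.to_numeric(frame["rna_yield_per_L"])
        present = frame["rna_yield_per_L"].notna()
        if (frame.loc[present, "rna_yield_per_L"] < 0).any():
            raise ValidationError("rna_yield_per_L must be nonnegative")
    for var in ENV_VARS:
        if var in frame.columns:
            frame[var] = pd.to_numeric(frame[var])
    return SampleTable(frame)


def write_samples(samples: SampleTable, path: str | Path) -> None:
    out = samples.frame.copy()
    out.index.name = "library_id"
    out.to_csv(path, sep="\t")


def read_counts(
    path: str | Path, catalog: UnigeneCatalog, samples: SampleTable
) -> pd.DataFrame:
    """Read a wide unigenes x libraries raw count matrix and reconcile its
    index sets against the catalog and the sample table.

    Unigenes absent from the catalog and library columns absent from the
    sample table are referential errors; catalog unigenes missing from the
    file get zero counts; every sample-table library must be present.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    unknown_unigenes = frame.index.difference(catalog.ids)
    if len(unknown_unigenes):
        raise ReferentialError(
            f"count matrix unigene '{unknown_unigenes[0]}' absent from catalog"
        )
    unknown_libs = frame.columns.difference(samples.ids)
    if len(unknown_libs):
        raise ReferentialError(
            f"count matrix library '{unknown_libs[0]}' absent from sample table"
        )
    missing_libs = samples.ids.difference(frame.columns)
    if len(missing_libs):
        raise ReferentialError(
            f"sample-table library '{missing_libs[0]}' missing from count matrix"
        )
    values = frame.to_numpy()
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValidationError("counts must be finite and nonnegative")
    if not np.allclose(values, np.round(values)):
        raise ValidationError("counts must be integers")
    counts = frame.astype(np.int64).reindex(index=catalog.ids, fill_value=0)
    return counts[list(samples.ids)]


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "unigene_id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
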