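"""Count-table containers, ingestion, rarefaction, filtering and aggregation.

The central container is :class:`CountTable`, a taxa x libraries matrix of
non-negative integer read counts, paired with a :class:`StudyDesign` that maps
each sequencing library to the fish (host individual) it came from, that
fish's full-sib family and source population, the DNA-isolation protocol used,
and the experiment arm (reproducibility vs precision).

All normalisation here is by rarefaction: libraries are downsampled without
replacement (multivariate hypergeometric) to a common depth so that read
totals are fixed and alpha/beta diversity values are comparable across
libraries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNASSIGNED_LABEL = "Unassigned"

__all__ = [
    "CountTable",
    "StudyDesign",
    "rarefy",
    "drop_incomplete_fish",
    "filter_taxa_by_count",
    "filter_taxa_by_fish_prevalence",
    "filter_taxa_by_label",
    "aggregate_by_taxonomy",
    "rarefaction_curve",
    "DEFAULT_MIN_COUNT",
    "DEFAULT_MIN_LIBRARIES",
    "DEFAULT_MIN_FISH",
    "PRIMARY_RAREFACTION_DEPTH",
    "ASV_RAREFACTION_DEPTH",
]

# Filter presets for replicated amplicon designs of this shape: taxa kept if
# they reach at least five reads in at least nine libraries (taxon effect
# tests), or appear in at least 10 fish (per-taxon repeatability); libraries
# downsampled to 105,000 reads (primary OTU tables) or 74,300 (denoised ASVs).
DEFAULT_MIN_COUNT = 5
DEFAULT_MIN_LIBRARIES = 9
DEFAULT_MIN_FISH = 10
PRIMARY_RAREFACTION_DEPTH = 105_000
ASV_RAREFACTION_DEPTH = 74_300


@dataclass
class CountTable:
    """Taxa x libraries matrix of non-negative integer counts.

    Parameters
    ----------
    taxon_ids : list of str
        Unique taxon (OTU/ASV/taxonomy-group) identifiers, one per row.
    library_ids : list of str
        Unique sequencing-library identifiers, one per column.
    counts : ndarray of shape (n_taxa, n_libraries)
        Non-negative integer read counts.
    taxonomy : dict, optional
        Map taxon id -> semicolon-delimited hierarchical label
        (e.g. ``"k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria"``).
    """

    taxon_ids: list
    library_ids: list
    counts: np.ndarray
    taxonomy: dict | None = None

    def __post_init__(self):
        self.taxon_ids = list(self.taxon_ids)
        self.library_ids = list(self.library_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.library_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.taxon_ids)} taxa x {len(self.library_ids)} libraries"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        if len(set(self.library_ids)) != len(self.library_ids):
            raise ValueError("duplicate library ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_libraries(self) -> int:
        return len(self.library_ids)

    def library_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, library_id: str) -> np.ndarray:
        return self.counts[:, self.library_ids.index(library_id)]

    def select_libraries(self, library_ids) -> "CountTable":
        idx = [self.library_ids.index(l) for l in library_ids]
        return CountTable(self.taxon_ids, list(library_ids),
                          self.counts[:, idx], self.taxonomy)

    def select_taxa(self, taxon_ids) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        taxonomy = None
        if self.taxonomy is not None:
            taxonomy = {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
        return CountTable(list(taxon_ids), self.library_ids,
                          self.counts[idx, :], taxonomy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids,
                            columns=self.library_ids)

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, taxonomy: dict | None = None) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(), taxonomy)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, taxonomy: dict | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_dataframe(df, taxonomy)

    def to_biom_json(self, path) -> None:
        """Write a dense BIOM-1.0-style JSON document."""
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "microrepeat",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [self.n_taxa, self.n_libraries],
            "rows": [
                {"id": t,
                 "metadata": ({"taxonomy": self.taxonomy[t].split(";")}
                              if self.taxonomy and t in self.taxonomy else None)}
                for t in self.taxon_ids
            ],
            "columns": [{"id": l, "metadata": None} for l in self.library_ids],
            "data": self.counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_biom_json(cls, path) -> "CountTable":
        with open(path) as fh:
            doc = json.load(fh)
        taxon_ids = [r["id"] for r in doc["rows"]]
        library_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        if doc["matrix_type"] == "dense":
            counts = np.asarray(doc["data"], dtype=np.int64)
        else:  # sparse [row, col, value] triples
            counts = np.zeros(shape, dtype=np.int64)
            for i, j, v in doc["data"]:
                counts[i, j] = v
        taxonomy = {}
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            if md.get("taxonomy"):
                taxonomy[r["id"]] = ";".join(md["taxonomy"])
        return cls(taxon_ids, library_ids, counts, taxonomy or None)


@dataclass
class StudyDesign:
    """Per-library experimental design: fish, family, population, protocol.

    Invariants: every analyzed library appears exactly once; each fish maps to
    exactly one family and one population. Family and rearing tank are
    confounded in the emulated design, so family effects cannot be separated
    from tank effects — a single family_id carries both.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("library_id", "fish_id", "family_id", "population",
                "protocol", "experiment")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.table["library_id"].duplicated().any():
            raise ValueError("duplicate library ids in design")
        per_fish = self.table.groupby("fish_id")[["family_id", "population"]].nunique()
        if (per_fish > 1).any().any():
            raise ValueError("a fish maps to multiple families or populations")
        self.table = self.table.reset_index(drop=True)

    @property
    def library_ids(self) -> list:
        return list(self.table["library_id"])

    def subset(self, library_ids) -> "StudyDesign":
        sub = self.table[self.table["library_id"].isin(set(library_ids))]
        # preserve requested order
        sub = sub.set_index("library_id").loc[list(library_ids)].reset_index()
        return StudyDesign(sub)

    def column_for(self, library_ids, column: str) -> np.ndarray:
        lut = self.table.set_index("library_id")[column]
        return lut.loc[list(library_ids)].to_numpy()

    def fish_for(self, library_ids) -> np.ndarray:
        return self.column_for(library_ids, "fish_id")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StudyDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"library_id": str,
                                                      "fish_id": str,
                                                      "family_id": str}))


# --------------------------------------------------------------------------
# preparation operations
# --------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int | np.random.Generator = 0):
    """Downsample every library to exactly `depth` reads without replacement.

    Libraries whose total is below `depth` are dropped. Returns
    ``(rarefied_table, dropped_library_ids)``. Sampling is a single
    multivariate-hypergeometric draw per library, seeded for reproducibility.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.library_totals()
    keep, dropped = [], []
    cols = []
    for j, lib in enumerate(table.library_ids):
        if totals[j] < depth:
            dropped.append(lib)
            continue
        keep.append(lib)
        col = table.counts[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    counts = (np.column_stack(cols) if cols
              else np.zeros((table.n_taxa, 0), dtype=np.int64))
    return CountTable(table.taxon_ids, keep, counts, table.taxonomy), dropped


def drop_incomplete_fish(table: CountTable, design: StudyDesign,
                         min_replicates: int = 1):
    """Drop whole fish that retain fewer than `min_replicates` libraries.

    Intended to run after `rarefy` has removed shallow libraries. Returns
    ``(table, design, audit)`` where audit lists removed fish and libraries.
    """
    design = design.subset([l for l in table.library_ids
                            if l in set(design.library_ids)])
    libs = design.library_ids
    fish = design.fish_for(libs)
    counts_per_fish = pd.Series(fish).value_counts()
    bad_fish = set(counts_per_fish[counts_per_fish < min_replicates].index)
    keep_libs = [l for l, f in zip(libs, fish) if f not in bad_fish]
    removed_libs = [l for l, f in zip(libs, fish) if f in bad_fish]
    audit = {"removed_fish": sorted(bad_fish),
             "removed_libraries": removed_libs,
             "n_fish_retained": int(counts_per_fish.ge(min_replicates).sum())}
    return table.select_libraries(keep_libs), design.subset(keep_libs), audit


def filter_taxa_by_count(table: CountTable, min_count: int = DEFAULT_MIN_COUNT,
                         min_libraries: int = DEFAULT_MIN_LIBRARIES) -> CountTable:
    """Keep taxa with >= min_count reads in >= min_libraries libraries.

    Defaults are the study preset (at least five counts in at least nine
    libraries).
    """
    if min_count < 0 or min_libraries < 0:
        raise ValueError("thresholds must be >= 0")
    ok = (table.counts >= min_count).sum(axis=1) >= min_libraries
    return table.select_taxa([t for t, k in zip(table.taxon_ids, ok) if k])


def filter_taxa_by_fish_prevalence(table: CountTable, design: StudyDesign,
                                   min_fish: int = DEFAULT_MIN_FISH) -> CountTable:
    """Keep taxa present (any replicate > 0) in at least `min_fish` fish."""
    fish = design.fish_for(table.library_ids)
    present = table.counts > 0
    fish_levels = pd.unique(fish)
    n_fish_present = np.zeros(table.n_taxa, dtype=int)
    for f in fish_levels:
        n_fish_present += present[:, fish == f].any(axis=1)
    ok = n_fish_present >= min_fish
    return table.select_taxa([t for t, k in zip(table.taxon_ids, ok) if k])


def filter_taxa_by_label(table: CountTable, blacklist=("mitochondria",
                                                       "chloroplast")) -> CountTable:
    """Drop taxa whose taxonomy label contains any blacklisted substring.

    Generic label filter standing in for host-organelle removal
    (mitochondria / chloroplast 16S amplicons).
    """
    if table.taxonomy is None:
        return table
    bl = tuple(b.lower() for b in blacklist)
    keep = [t for t in table.taxon_ids
            if not any(b in table.taxonomy.get(t, "").lower() for b in bl)]
    return table.select_taxa(keep)


def _label_prefix(label: str, level: int) -> str:
    ranks = [r.strip() for r in label.split(";")]
    ranks = ranks[:level]
    # a rank that is empty or a bare prefix like "s__" carries no assignment
    while ranks and (not ranks[-1] or ranks[-1].endswith("__")):
        ranks.pop()
    if not ranks:
        return UNASSIGNED_LABEL
    return ";".join(ranks)


def aggregate_by_taxonomy(table: CountTable, level: int) -> CountTable:
    """Sum counts over taxa sharing the taxonomy-label prefix to `level` ranks.

    Level follows the L-convention of taxonomy summary tables: level 2 is
    phylum, 3 class ("L3"), 7 species ("L7"). Taxa without a taxonomy label
    pool into "Unassigned". Per-library totals are conserved exactly.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    taxonomy = table.taxonomy or {}
    groups: dict[str, np.ndarray] = {}
    for i, t in enumerate(table.taxon_ids):
        label = _label_prefix(taxonomy.get(t, ""), level)
        if label in groups:
            groups[label] = groups[label] + table.counts[i]
        else:
            groups[label] = table.counts[i].astype(np.int64).copy()
    ids = sorted(groups)
    counts = np.vstack([groups[g] for g in ids])
    return CountTable(ids, table.library_ids, counts,
                      {g: g for g in ids if g != UNASSIGNED_LABEL})


def rarefaction_curve(table: CountTable, depths, metric, iterations: int = 10,
                      seed: int = 0) -> pd.DataFrame:
    """Mean `metric(column)` per library per depth over repeated rarefactions.

    `metric` is any callable on a count vector (e.g. `diversity.richness`).
    Depths exceeding a library's total yield NaN for that library. Returns a
    long-format DataFrame (library_id, depth, value).
    """
    rng = np.random.default_rng(seed)
    totals = table.library_totals()
    records = []
    for j, lib in enumerate(table.library_ids):
        col = table.counts[:, j]
        for depth in depths:
            if depth > totals[j]:
                records.append((lib, depth, np.nan))
                continue
            if depth == totals[j]:
                records.append((lib, depth, float(metric(col))))
                continue
            vals = [metric(rng.multivariate_hypergeometric(col, int(depth)))
                    for _ in range(iterations)]
            records.append((lib, depth, float(np.mean(vals))))
    return pd.DataFrame(records, columns=["library_id", "depth", "value"])
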