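"""Count-table data model, filters, compositional transforms, and TSV I/O.

The :class:`CountTable` (samples x taxa, non-negative integers, optional
per-taxon lineage) is the substrate every analysis stage operates on.
All files are plain UTF-8 tab-separated text with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: lineage labels that mark organellar reads to be discarded
_ORGANELLE_LABELS = frozenset({"chloroplast", "mitochondria", "mitochondrion"})


@dataclass
class CountTable:
    """Samples x taxa matrix of sequence counts with optional lineage.

    Parameters
    ----------
    sample_ids : list of str
        Ordered, unique sample labels (rows).
    taxon_ids : list of str
        Ordered, unique taxon labels (columns).
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer counts.
    lineage : dict, optional
        Per-taxon mapping ``taxon_id -> {rank: name or None}`` using the
        ranks in :data:`RANKS`. Missing taxa are treated as fully
        unassigned.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    lineage: dict[str, dict[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_s, n_t = self.counts.shape
        if n_s != len(self.sample_ids) or n_t != len(self.taxon_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != n_t:
            raise ValueError("duplicate taxon IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.taxon_ids
        )

    def genus_label(self, taxon_id: str) -> str:
        """Label at genus rank, falling back to the lowest assigned rank.

        Unassigned-genus taxa get ``"<lowest rank>_unclassified"`` so they
        stay distinct agglomeration units.
        """
        lin = self.lineage.get(taxon_id, {})
        genus = lin.get("genus")
        if genus:
            return genus
        for rank in reversed(RANKS[:-1]):
            name = lin.get(rank)
            if name:
                return f"{name}_unclassified"
        return f"{taxon_id}_unclassified"


@dataclass
class SampleMetadata:
    """Per-sample design variables driving every grouped analysis."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "mouse_id", "week", "phase", "tolerance", "batch")
    PHASES = ("pre", "early", "mid", "late", "post")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        bad = set(self.frame["phase"]) - set(self.PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    def aligned_to(self, table: CountTable) -> pd.DataFrame:
        """Metadata rows reordered to the table's sample order."""
        idx = self.frame.set_index("sample_id")
        missing = [s for s in table.sample_ids if s not in idx.index]
        if missing:
            raise ValueError(f"samples absent from metadata: {missing[:5]}")
        return idx.loc[table.sample_ids].reset_index()

    def column_for(self, table: CountTable, name: str) -> np.ndarray:
        return self.aligned_to(table)[name].to_numpy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_count_table(table: CountTable, path) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_count_table(path, taxonomy=None) -> CountTable:
    """Read a counts TSV (rows = samples, columns = taxa).

    Raises on ragged rows, duplicate IDs, or negative / non-integer counts.
    ``taxonomy`` optionally points to a lineage TSV written by
    :func:`write_taxonomy`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing entries")
    lineage = read_taxonomy(taxonomy) if taxonomy is not None else {}
    return CountTable(
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        counts=df.to_numpy(),
        lineage=lineage,
    )


def write_taxonomy(lineage: dict, path) -> None:
    rows = []
    for taxon, lin in lineage.items():
        rows.append([taxon] + [lin.get(r) or "" for r in RANKS])
    pd.DataFrame(rows, columns=["taxon_id", *RANKS]).to_csv(
        path, sep="\t", index=False
    )


def read_taxonomy(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    lineage = {}
    for _, row in df.iterrows():
        lineage[row["taxon_id"]] = {
            r: (row[r] if row[r] else None) for r in RANKS
        }
    return lineage


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Filters and agglomeration
# ---------------------------------------------------------------------------

def filter_taxa(table: CountTable, min_total: int = 3) -> CountTable:
    """Taxonomic + abundance filter.

    Drops taxa with an unassigned phylum, lineages containing chloroplast
    or mitochondria labels, and taxa whose total count across the whole
    table is below ``min_total`` (default removes singletons and
    doubletons). Samples are untouched. Idempotent.
    """
    keep = []
    totals = table.counts.sum(axis=0)
    for j, taxon in enumerate(table.taxon_ids):
        lin = table.lineage.get(taxon, {})
        if not lin.get("phylum"):
            continue
        labels = {str(v).lower() for v in lin.values() if v}
        if labels & _ORGANELLE_LABELS:
            continue
        if totals[j] < min_total:
            continue
        keep.append(j)
    return CountTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=[table.taxon_ids[j] for j in keep],
        counts=table.counts[:, keep],
        lineage={t: table.lineage[t] for t in
                 (table.taxon_ids[j] for j in keep) if t in table.lineage},
    )


def agglomerate_genus(table: CountTable) -> CountTable:
    """Sum counts of taxa sharing a genus label (lexicographic columns).

    Unassigned-genus taxa keep a ``<lowest rank>_unclassified`` label so
    they remain distinct units. Total count is conserved.
    """
    labels = [table.genus_label(t) for t in table.taxon_ids]
    order = sorted(set(labels))
    pos = {g: i for i, g in enumerate(order)}
    out = np.zeros((len(table.sample_ids), len(order)), dtype=np.int64)
    lineage: dict[str, dict[str, str | None]] = {}
    for j, (taxon, label) in enumerate(zip(table.taxon_ids, labels)):
        out[:, pos[label]] += table.counts[:, j]
        lineage.setdefault(label, dict(table.lineage.get(taxon, {})))
    return CountTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=order,
        counts=out,
        lineage=lineage,
    )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def relative_abundance(table: CountTable) -> np.ndarray:
    """Rows closed to sum 1. Raises on all-zero samples."""
    totals = table.counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        zero = [table.sample_ids[i] for i in np.flatnonzero(totals[:, 0] == 0)]
        raise ValueError(f"all-zero samples: {zero[:5]}")
    return table.counts / totals


def clr_transform(table: CountTable, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio after adding ``pseudocount`` to every count.

    Each output row sums to zero (within numerical tolerance).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    comp = table.counts + pseudocount
    comp = comp / comp.sum(axis=1, keepdims=True)
    logs = np.log(comp)
    return logs - logs.mean(axis=1, keepdims=True)


def presence_absence(table: CountTable) -> np.ndarray:
    return (table.counts > 0).astype(np.int8)


def shared_membership(groups: dict[str, list[str]],
                      table: CountTable) -> dict[frozenset, int]:
    """Venn-region taxon counts for named groups of samples.

    A taxon belongs to a group if it is present (count > 0) in at least
    one of the group's samples. Keys are frozensets of group names; the
    value counts taxa present in exactly that set of groups. Region
    counts partition the union of all member taxa.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}
    membership: dict[str, np.ndarray] = {}
    for name, samples in groups.items():
        if not samples:
            raise ValueError(f"group {name!r} is empty")
        rows = [sample_pos[s] for s in samples]
        membership[name] = table.counts[rows].sum(axis=0) > 0
    regions: dict[frozenset, int] = {}
    names = list(groups)
    stacked = np.stack([membership[n] for n in names])
    for j in range(stacked.shape[1]):
        present = frozenset(n for i, n in enumerate(names) if stacked[i, j])
        if present:
            regions[present] = regions.get(present, 0) + 1
    return regions


def subset_samples(table: CountTable, keep: list[str]) -> CountTable:
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    rows = [pos[s] for s in keep]
    return replace(table, sample_ids=list(keep), counts=table.counts[rows])
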