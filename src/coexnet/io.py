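"""Tabular and graph I/O.

All tables are UTF-8 tab-separated files with '.' as the decimal separator
and no quoting.  Count tables and sample frames round-trip exactly (floats
are written with pandas' minimal round-trip representation).  Networks are
written as three files per network directory:

* ``edges.tsv`` — canonical edge records (lexicographic node order, sorted),
  Spearman weights at 6 significant digits, Monte-Carlo support at 3 decimals;
* ``nodes.tsv`` — one row per non-isolated node with its annotations;
* ``network.graphml`` — the same graph with attributes, for Gephi import.
"""

from __future__ import annotations

import json
import math
import os
import unicodedata
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "CountTable",
    "SampleFrame",
    "TaxonomyTable",
    "TraitTable",
    "EdgeRecord",
    "HABITATS",
    "LOCALITIES",
    "SUBSTRATES",
    "GROUPS",
    "SOIL_VARS",
    "read_count_table",
    "write_count_table",
    "read_sample_frame",
    "write_sample_frame",
    "read_taxonomy",
    "write_taxonomy",
    "read_traits",
    "write_traits",
    "write_network",
    "read_network",
    "write_analysis_matrix",
    "read_analysis_matrix",
    "round_sig",
]

HABITATS = ("terra-firme", "campina", "varzea", "igapo")
LOCALITIES = ("BC", "JAU", "CUI", "CXN")
SUBSTRATES = ("litter", "soil")
GROUPS = ("Bacteria", "Fungi", "Protist", "Metazoa", "Chloroplastida", "Unknown")

#: Soil physicochemical variables carried by a sample frame.  SB is the sum of
#: exchangeable bases, V the base-saturation index, m the aluminum-saturation
#: index, t/T the effective/total cation exchange capacity.
SOIL_VARS = (
    "pH", "C", "P", "Na", "K", "Ca", "Mg", "SB",
    "Al", "H_Al", "m", "V", "t", "T", "texture",
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def round_sig(x: float, digits: int = 6) -> float:
    """Round ``x`` to ``digits`` significant digits (0 and non-finite pass through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"%.{digits}g" % x)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """An OTU-by-sample read count matrix for one marker / sequencing run.

    ``counts`` is indexed ``[otu, sample]`` and is non-negative; raw input is
    integer-valued, post-normalization values are real.
    """

    marker_id: str
    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        for kind, ids in (("OTU", self.otu_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {kind} id: {i!r}")
                seen.add(i)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        bad = ~np.isfinite(self.counts) | (self.counts < 0)
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"negative or non-finite count at OTU {self.otu_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}: {self.counts[r, c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return CountTable(self.marker_id, list(self.otu_ids), list(sample_ids),
                          self.counts[:, idx])

    def select_otus(self, otu_ids: list[str]) -> "CountTable":
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return CountTable(self.marker_id, list(otu_ids), list(self.sample_ids),
                          self.counts[idx, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.marker_id == other.marker_id
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_count_table(path: str | os.PathLike, marker_id: str | None = None) -> CountTable:
    """Read an OTU-by-sample TSV (first column OTU ids, header sample ids).

    Row and column order from the file is preserved.  ``marker_id`` defaults
    to the file's stem.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    otu_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().to_numpy()
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"{path}: cell at OTU {otu_ids[r]!r}, sample {sample_ids[c]!r} "
            f"does not parse as a number: {df.iat[r, c]!r}"
        )
    if marker_id is None:
        marker_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    try:
        # exact float parsing (pd.to_numeric above is only used to locate bad
        # cells; its fast path is not correctly rounded)
        return CountTable(marker_id, otu_ids, sample_ids,
                          df.astype(float).to_numpy())
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_count_table(table: CountTable, path: str | os.PathLike) -> None:
    df = table.to_frame()
    # integral matrices (raw read counts) are written without a decimal point
    if np.array_equal(df.to_numpy(), np.floor(df.to_numpy())):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="otu_id")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_REQUIRED_SAMPLE_COLS = ("sample_id", "plot_id", "locality", "habitat", "substrate")


def _fold(value: str) -> str:
    """Case/accent-insensitive canonical key (várzea → varzea)."""
    s = unicodedata.normalize("NFD", str(value).strip())
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    return s.lower().replace(" ", "-").replace("_", "-")


def _canon_enum(value: str, allowed: tuple[str, ...], what: str) -> str:
    folded = _fold(value)
    for a in allowed:
        if _fold(a) == folded:
            return a
    raise ValidationError(
        f"unknown {what} {value!r}; allowed values: {', '.join(allowed)}"
    )


@dataclass
class SampleFrame:
    """Per-sample metadata: plot, locality, habitat, substrate and soil variables.

    ``data`` holds one row per sample in study order; ``soil_vars`` names the
    numeric soil physicochemistry columns present (identical key-set across
    samples; a variable missing for some samples is dropped with a warning
    at assembly time).
    """

    data: pd.DataFrame
    soil_vars: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in _REQUIRED_SAMPLE_COLS:
            if col not in self.data.columns:
                raise FormatError(f"sample frame lacks mandatory column {col!r}")
        ids = list(self.data["sample_id"])
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data["sample_id"]]

    def habitat_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["habitat"]))

    def locality_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["locality"]))

    def plot_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["plot_id"]))

    def env_matrix(self, env_vars: list[str] | None = None) -> pd.DataFrame:
        """Soil variables as a (variable x sample) frame."""
        names = list(env_vars) if env_vars is not None else list(self.soil_vars)
        missing = [v for v in names if v not in self.data.columns]
        if missing:
            raise ValidationError(f"soil variables not in sample frame: {missing}")
        sub = self.data.set_index("sample_id")[names]
        return sub.T

    def subset(self, sample_ids: list[str]) -> "SampleFrame":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return SampleFrame(keep.copy(), list(self.soil_vars))


def read_sample_frame(path: str | os.PathLike) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_SAMPLE_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    df["habitat"] = [_canon_enum(v, HABITATS, "habitat") for v in df["habitat"]]
    df["locality"] = [_canon_enum(v, LOCALITIES, "locality") for v in df["locality"]]
    df["substrate"] = [_canon_enum(v, SUBSTRATES, "substrate") for v in df["substrate"]]
    soil = [c for c in df.columns if c not in _REQUIRED_SAMPLE_COLS]
    for c in soil:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return SampleFrame(df, soil)


def write_sample_frame(frame: SampleFrame, path: str | os.PathLike) -> None:
    frame.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# taxonomy and traits
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTable:
    """otu_id → (group, phylum, class_or_order); missing OTUs resolve to Unknown."""

    records: dict[str, tuple[str, str, str]]

    def group_of(self, otu_id: str, warn: bool = True) -> str:
        rec = self.records.get(otu_id)
        if rec is None:
            if warn:
                warnings.warn(f"OTU {otu_id!r} absent from taxonomy; assigned Unknown")
            return "Unknown"
        return rec[0]

    def phylum_of(self, otu_id: str) -> str:
        rec = self.records.get(otu_id)
        return rec[1] if rec else ""

    def class_of(self, otu_id: str) -> str:
        rec = self.records.get(otu_id)
        return rec[2] if rec else ""


def read_taxonomy(path: str | os.PathLike) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("otu_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    recs: dict[str, tuple[str, str, str]] = {}
    for _, row in df.iterrows():
        group = _canon_enum(row["group"], GROUPS, "taxonomic group")
        recs[str(row["otu_id"])] = (
            group,
            str(row.get("phylum", "") or ""),
            str(row.get("class_or_order", "") or ""),
        )
    return TaxonomyTable(recs)


def write_taxonomy(tax: TaxonomyTable, path: str | os.PathLike) -> None:
    rows = [
        {"otu_id": o, "group": g, "phylum": p, "class_or_order": c}
        for o, (g, p, c) in tax.records.items()
    ]
    pd.DataFrame(rows, columns=["otu_id", "group", "phylum", "class_or_order"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class TraitTable:
    """otu_id → single dominant functional trait label."""

    traits: dict[str, str]

    def trait_of(self, otu_id: str) -> str:
        return self.traits.get(otu_id, "")


def read_traits(path: str | os.PathLike) -> TraitTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("otu_id", "trait"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    ids = list(df["otu_id"])
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValidationError(f"{path}: OTU {dup!r} has more than one trait row")
    return TraitTable(dict(zip(df["otu_id"], df["trait"])))


def write_traits(traits: TraitTable, path: str | os.PathLike) -> None:
    pd.DataFrame(
        [{"otu_id": o, "trait": t} for o, t in traits.traits.items()],
        columns=["otu_id", "trait"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# analysis matrices
# ---------------------------------------------------------------------------


def write_analysis_matrix(matrix, path: str | os.PathLike) -> None:
    """Persist an assembled analysis matrix as TSV (row_id, kind, samples...)."""
    df = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
    df.insert(0, "kind", list(matrix.row_kind))
    df.insert(0, "row_id", matrix.row_ids)
    df.to_csv(path, sep="\t", index=False)


def read_analysis_matrix(path: str | os.PathLike):
    from .preprocess import AnalysisMatrix

    df = pd.read_csv(path, sep="\t", dtype={"row_id": str, "kind": str},
                     float_precision="round_trip")
    for col in ("row_id", "kind"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    samples = [c for c in df.columns if c not in ("row_id", "kind")]
    values = df[samples].to_numpy(dtype=float)
    return AnalysisMatrix(list(df["row_id"]), np.array(df["kind"], dtype=object),
                          values, samples)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EdgeRecord:
    """One signed consensus edge.

    ``node_a < node_b`` lexicographically; sign 'pos' iff weight > 0; support
    is the fraction of Monte-Carlo samples containing the edge.
    """

    node_a: str
    node_b: str
    sign: str
    weight: float
    support: float

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValidationError(
                f"edge nodes not in canonical order: {self.node_a!r} !< {self.node_b!r}"
            )
        if self.sign not in ("pos", "neg"):
            raise ValidationError(f"edge sign must be 'pos' or 'neg', got {self.sign!r}")
        if (self.sign == "pos") != (self.weight > 0):
            raise ValidationError(
                f"sign {self.sign!r} inconsistent with weight {self.weight!r}"
            )
        if not 0.0 <= self.support <= 1.0:
            raise ValidationError(f"support {self.support!r} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.node_a, self.node_b, self.sign)


_NODE_COLS = ("node_id", "kind", "group", "phylum", "trait", "abundance", "degree")


def write_network(net, outdir: str | os.PathLike) -> dict[str, str]:
    """Write a finalized SignedNetwork as edges.tsv + nodes.tsv + network.graphml.

    Output is byte-stable for a fixed network: edges are sorted canonically,
    weights carry 6 significant digits and support 3 decimals.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    edges = sorted(net.edges, key=lambda e: e.key)
    epath = os.path.join(outdir, "edges.tsv")
    with open(epath, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tsign\tweight\tsupport\n")
        for e in edges:
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.sign}\t{e.weight:.6g}\t{e.support:.3f}\n")
    npath = os.path.join(outdir, "nodes.tsv")
    with open(npath, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_NODE_COLS) + "\n")
        for n in sorted(net.nodes, key=lambda n: n.id):
            fh.write(
                f"{n.id}\t{n.kind}\t{n.group}\t{n.phylum}\t{n.trait}\t"
                f"{n.abundance:.6g}\t{n.degree}\n"
            )
    g = nx.Graph()
    for n in sorted(net.nodes, key=lambda n: n.id):
        g.add_node(n.id, kind=n.kind, group=n.group, phylum=n.phylum,
                   trait=n.trait, abundance=float(n.abundance), degree=int(n.degree))
    for e in edges:
        g.add_edge(e.node_a, e.node_b, sign=e.sign, weight=float(e.weight),
                   support=float(e.support))
    gpath = os.path.join(outdir, "network.graphml")
    nx.write_graphml(g, gpath)
    return {"edges": epath, "nodes": npath, "graphml": gpath}


def read_network(indir: str | os.PathLike):
    """Re-read a network directory written by :func:`write_network`."""
    from .nullmodel import NodeRecord, SignedNetwork, Thresholds

    indir = os.fspath(indir)
    edf = pd.read_csv(os.path.join(indir, "edges.tsv"), sep="\t", dtype=str)
    edges = [
        EdgeRecord(r["node_a"], r["node_b"], r["sign"], float(r["weight"]),
                   float(r["support"]))
        for _, r in edf.iterrows()
    ]
    ndf = pd.read_csv(os.path.join(indir, "nodes.tsv"), sep="\t", dtype=str).fillna("")
    nodes = [
        NodeRecord(r["node_id"], r["kind"], r["group"], r["phylum"], r["trait"],
                   float(r["abundance"]), int(r["degree"]))
        for _, r in ndf.iterrows()
    ]
    tpath = os.path.join(indir, "thresholds.json")
    thresholds = Thresholds(float("nan"), float("nan"))
    if os.path.exists(tpath):
        with open(tpath, encoding="utf-8") as fh:
            d = json.load(fh)
        thresholds = Thresholds(float(d.get("t_pos", "nan")), float(d.get("t_neg", "nan")))
    return SignedNetwork(nodes=nodes, edges=edges, thresholds=thresholds, config=None)
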