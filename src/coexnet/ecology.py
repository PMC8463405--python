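"""Habitat breadth classification, per-habitat networks and composition tables.

An OTU is a habitat *specialist* if its reads occur in exactly one of the
four habitat types, a *generalist* if it occurs in at least three; the
residual two-habitat class is labeled *intermediate*.  Occurrence is defined
on raw (pre-normalization) counts: any read in any sample of a habitat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable, SampleFrame, TaxonomyTable, TraitTable
from .nullmodel import NullModelConfig, SignedNetwork, infer_network, with_seed
from .preprocess import assemble, expected_depth, filter_low_abundance, normalize

__all__ = [
    "BreadthClass",
    "classify_breadth",
    "run_pipeline",
    "subset_and_infer",
    "composition_summary",
    "breadth_summary",
]


@dataclass(frozen=True)
class BreadthClass:
    otu_id: str
    n_habitats: int
    n_plots: int
    label: str  # specialist | intermediate | generalist


def _label(n_habitats: int) -> str:
    if n_habitats == 1:
        return "specialist"
    if n_habitats >= 3:
        return "generalist"
    return "intermediate"


def classify_breadth(tables: list[CountTable],
                     frame: SampleFrame) -> list[BreadthClass]:
    """One record per OTU observed anywhere; OTUs absent from every sample of
    the frame are excluded with a warning."""
    habitat = frame.habitat_of()
    plot = frame.plot_of()
    out: list[BreadthClass] = []
    skipped: list[str] = []
    for t in tables:
        cols = [j for j, s in enumerate(t.sample_ids) if s in habitat]
        habs = [habitat[t.sample_ids[j]] for j in cols]
        plots = [plot[t.sample_ids[j]] for j in cols]
        present = t.counts[:, cols] > 0
        for i, otu in enumerate(t.otu_ids):
            hit = present[i]
            if not hit.any():
                skipped.append(otu)
                continue
            n_hab = len({h for h, on in zip(habs, hit) if on})
            n_plots = len({p for p, on in zip(plots, hit) if on})
            out.append(BreadthClass(otu, n_hab, n_plots, _label(n_hab)))
    if skipped:
        warnings.warn(f"{len(skipped)} OTUs with no occurrence were excluded "
                      f"from breadth classification (e.g. {skipped[:3]})")
    return out


def run_pipeline(
    tables: list[CountTable],
    frame: SampleFrame,
    cfg: NullModelConfig,
    env_vars: list[str] | None = None,
    taxonomy: TaxonomyTable | None = None,
    traits: TraitTable | None = None,
    depth_factor: float = 0.5,
    filter_fraction: float = 0.10,
) -> SignedNetwork:
    """normalize → filter → assemble → infer, per marker then jointly."""
    processed = []
    for t in tables:
        nt = normalize(t, expected_depth(t, depth_factor))
        processed.append(filter_low_abundance(nt, filter_fraction))
    matrix = assemble(processed, frame, env_vars)
    return infer_network(matrix, cfg, taxonomy=taxonomy, traits=traits)


def subset_and_infer(
    tables: list[CountTable],
    frame: SampleFrame,
    cfg: NullModelConfig,
    by: str = "habitat",
    env_vars: list[str] | None = None,
    taxonomy: TaxonomyTable | None = None,
    traits: TraitTable | None = None,
    min_samples: int = 3,
    **pipeline_kwargs,
) -> dict[str, SignedNetwork]:
    """Re-run the whole pipeline per habitat (or habitat within locality).

    Each subset keeps only its own samples and the OTUs recorded (count > 0)
    in them, and re-derives its own thresholds.  Subsets with fewer than
    ``min_samples`` samples are skipped with a warning.
    """
    if by not in ("habitat", "habitat_locality"):
        raise ValueError("by must be 'habitat' or 'habitat_locality'")
    d = frame.data
    if by == "habitat":
        groups = {str(h): list(d.loc[d["habitat"] == h, "sample_id"])
                  for h in sorted(d["habitat"].unique())}
    else:
        groups = {}
        for (h, loc), sub in d.groupby(["habitat", "locality"], sort=True):
            groups[f"{h}/{loc}"] = list(sub["sample_id"])

    out: dict[str, SignedNetwork] = {}
    for gi, (key, samples) in enumerate(sorted(groups.items())):
        if len(samples) < min_samples:
            warnings.warn(f"subset {key!r} has only {len(samples)} samples; skipped")
            continue
        sub_tables = []
        for t in tables:
            shared = [s for s in t.sample_ids if s in set(samples)]
            st = t.select_samples(shared)
            recorded = [o for o, tot in zip(st.otu_ids, st.otu_totals()) if tot > 0]
            if recorded:
                sub_tables.append(st.select_otus(recorded))
        if not sub_tables:
            warnings.warn(f"subset {key!r} has no recorded OTUs; skipped")
            continue
        sub_cfg = with_seed(cfg, cfg.seed + 1000 * (gi + 1))
        out[key] = run_pipeline(sub_tables, frame.subset(samples), sub_cfg,
                                env_vars=env_vars, taxonomy=taxonomy,
                                traits=traits, **pipeline_kwargs)
    return out


def composition_summary(
    net: SignedNetwork,
    taxonomy: TaxonomyTable | None = None,
    traits: TraitTable | None = None,
    breadth: list[BreadthClass] | None = None,
) -> pd.DataFrame:
    """Per-group composition of a network: node counts and proportions,
    edge-endpoint counts, and generalist/specialist proportions among the
    group's nodes."""
    by_id = {b.otu_id: b.label for b in (breadth or [])}
    rows = []
    groups: dict[str, dict] = {}
    endpoint: dict[str, int] = {}
    node_group: dict[str, str] = {}
    for n in net.nodes:
        g = ("env" if n.kind == "env"
             else (taxonomy.group_of(n.id, warn=False) if taxonomy else n.group))
        node_group[n.id] = g
        rec = groups.setdefault(g, {"n_nodes": 0, "generalist": 0, "specialist": 0})
        rec["n_nodes"] += 1
        lab = by_id.get(n.id)
        if lab in ("generalist", "specialist"):
            rec[lab] += 1
    for e in net.edges:
        for nid in (e.node_a, e.node_b):
            g = node_group.get(nid, "Unknown")
            endpoint[g] = endpoint.get(g, 0) + 1
    total_nodes = sum(rec["n_nodes"] for rec in groups.values()) or 1
    for g in sorted(groups):
        rec = groups[g]
        n = rec["n_nodes"]
        rows.append({
            "group": g,
            "n_nodes": n,
            "prop_nodes": n / total_nodes,
            "edge_endpoints": endpoint.get(g, 0),
            "n_generalist": rec["generalist"],
            "prop_generalist": rec["generalist"] / n if n else np.nan,
            "n_specialist": rec["specialist"],
            "prop_specialist": rec["specialist"] / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def breadth_summary(breadth: list[BreadthClass],
                    taxonomy: TaxonomyTable | None = None) -> pd.DataFrame:
    """Whole-dataset summary independent of any network: per taxonomic group,
    total OTUs and generalist/specialist counts with proportions."""
    rows_by_group: dict[str, dict] = {}
    for b in breadth:
        g = taxonomy.group_of(b.otu_id, warn=False) if taxonomy else "All"
        for key in ("All", g):
            rec = rows_by_group.setdefault(
                key, {"total": 0, "generalist": 0, "specialist": 0})
            rec["total"] += 1
            if b.label in ("generalist", "specialist"):
                rec[b.label] += 1
    rows = []
    order = ["All"] + sorted(k for k in rows_by_group if k != "All")
    for g in order:
        rec = rows_by_group[g]
        t = rec["total"]
        rows.append({
            "group": g, "total": t,
            "generalist": rec["generalist"],
            "prop_generalist": rec["generalist"] / t if t else np.nan,
            "specialist": rec["specialist"],
            "prop_specialist": rec["specialist"] / t if t else np.nan,
        })
    return pd.DataFrame(rows)
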