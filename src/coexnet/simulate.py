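"""Synthetic multi-marker metabarcoding communities with planted structure.

The generator emulates a plot-based soil/litter survey: a set of localities,
each holding a subset of four Amazonian habitat types, with a fixed number of
plots per habitat and two substrate samples (litter, mineral soil) per plot.
Abundances follow a latent Gaussian factor model: OTUs of a planted module
share one standard-normal factor per sample, so their log-abundances — and
hence any monotone transform of them — are positively rank-correlated with a
strength set by the module loading.  Exclusion pairs load on a shared factor
with opposite signs.  Read counts are drawn multinomially per sample at a
log-normal sequencing depth, which reproduces the compositional closure of
real amplicon data.  Soil variables can be tied to module factors, giving
planted OTU–environment correlations.

Everything is driven by one :class:`numpy.random.Generator` (PCG64) seeded
from the spec, so a fixed seed reproduces every table byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GROUPS,
    CountTable,
    SampleFrame,
    TaxonomyTable,
    TraitTable,
    ValidationError,
)

__all__ = [
    "MarkerSpec",
    "PlantedModule",
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticData",
    "generate",
    "generate_null",
    "study_spec",
    "benchmark_spec",
]


@dataclass(frozen=True)
class MarkerSpec:
    marker_id: str
    mean_depth: float
    depth_cv: float


@dataclass(frozen=True)
class PlantedModule:
    """A block of OTUs sharing one latent factor.

    ``loading`` in (0, 1] scales the shared factor in log-abundance space;
    ``marker_mix``/``group_mix`` spread the members over markers and
    taxonomic groups (uniform over available markers / a soil-like group mix
    when omitted).
    """

    size: int
    loading: float
    marker_mix: dict[str, float] | None = None
    group_mix: dict[str, float] | None = None

    def validate(self, markers: list[str]) -> None:
        if self.size < 2:
            raise ValidationError(f"module size must be >= 2, got {self.size}")
        if not 0 < self.loading <= 1:
            raise ValidationError(f"module loading must be in (0, 1], got {self.loading}")
        for mix, universe, what in (
            (self.marker_mix, markers, "marker"),
            (self.group_mix, list(GROUPS), "group"),
        ):
            if mix is None:
                continue
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValidationError(f"module {what}_mix proportions must sum to 1")
            unknown = set(mix) - set(universe)
            if unknown:
                raise ValidationError(f"module {what}_mix names unknown keys: {unknown}")


_DEFAULT_GROUP_MIX = {
    "Bacteria": 0.40, "Fungi": 0.20, "Protist": 0.15,
    "Metazoa": 0.13, "Chloroplastida": 0.02, "Unknown": 0.10,
}

_PHYLA = {
    "Bacteria": ("Proteobacteria", "Acidobacteria", "Actinobacteria",
                 "Planctomycetes", "Firmicutes"),
    "Fungi": ("Ascomycota", "Basidiomycota", "Mortierellomycota"),
    "Protist": ("Cercozoa", "Ciliophora", "Apicomplexa"),
    "Metazoa": ("Nematoda", "Arthropoda", "Annelida"),
    "Chloroplastida": ("Chlorophyta",),
    "Unknown": ("",),
}

_TRAITS = {
    "Bacteria": ("chemoheterotrophy", "fermentation", "nitrogen_fixation",
                 "cellulolysis"),
    "Fungi": ("saprotroph", "ectomycorrhizal", "plant_pathogen"),
    "Protist": ("bacterivore", "omnivore"),
    "Metazoa": ("bacterivore", "predator"),
    "Chloroplastida": ("phototroph",),
    "Unknown": ("",),
}

#: Habitat-specific soil baselines (mean values before noise): pH, organic
#: carbon (%), phosphorus (mg/kg), base cations (cmolc/kg), exchangeable Al,
#: potential acidity H+Al, clay fraction (%).  Várzea is the fertile
#: white-water floodplain; campina the acid white-sand soil.
_SOIL_BASE = {
    "terra-firme": dict(pH=4.0, C=2.0, P=4.0, Na=0.04, K=0.12, Ca=0.25, Mg=0.15,
                        Al=1.6, H_Al=7.0, texture=45.0),
    "campina":     dict(pH=3.6, C=1.2, P=2.5, Na=0.03, K=0.06, Ca=0.10, Mg=0.06,
                        Al=1.1, H_Al=5.0, texture=8.0),
    "varzea":      dict(pH=5.4, C=2.6, P=14.0, Na=0.10, K=0.30, Ca=6.0, Mg=1.8,
                        Al=0.3, H_Al=4.0, texture=35.0),
    "igapo":       dict(pH=3.9, C=3.0, P=5.0, Na=0.05, K=0.14, Ca=0.30, Mg=0.20,
                        Al=1.8, H_Al=8.0, texture=25.0),
}


@dataclass
class SyntheticSpec:
    """Full description of one synthetic study; the seed fixes every output."""

    localities: list[str]
    habitats_per_locality: dict[str, list[str]]
    plots_per_habitat: int
    markers: list[MarkerSpec]
    n_background_otus: int
    modules: list[PlantedModule]
    n_exclusion_pairs: int = 0
    exclusion_loading: float = 0.9
    env_link: list[tuple[int, str, float]] = field(default_factory=list)
    rare_fraction: float = 0.0
    seed: int = 0
    mu_sd: float = 1.0       # between-OTU log-abundance spread
    noise_sd: float = 0.5    # within-OTU residual log-abundance noise

    def validate(self) -> None:
        if not self.localities or not self.markers:
            raise ValidationError("spec needs at least one locality and one marker")
        if self.plots_per_habitat <= 0 or self.n_background_otus < 0:
            raise ValidationError("plots_per_habitat must be positive and "
                                  "n_background_otus non-negative")
        if not 0 <= self.rare_fraction <= 1:
            raise ValidationError(f"rare_fraction must be in [0, 1], got {self.rare_fraction}")
        if not 0 < self.exclusion_loading <= 1:
            raise ValidationError("exclusion_loading must be in (0, 1]")
        marker_ids = [m.marker_id for m in self.markers]
        if len(marker_ids) != len(set(marker_ids)):
            raise ValidationError("duplicate marker ids")
        for m in self.markers:
            if m.mean_depth <= 0 or m.depth_cv < 0:
                raise ValidationError(f"invalid depth parameters for marker {m.marker_id}")
        for loc in self.localities:
            if loc not in self.habitats_per_locality:
                raise ValidationError(f"no habitats listed for locality {loc!r}")
        for mod in self.modules:
            mod.validate(marker_ids)
        for k, _var, a in self.env_link:
            if not 0 <= k < len(self.modules):
                raise ValidationError(f"env_link refers to unknown module index {k}")
            if not -1 <= a <= 1:
                raise ValidationError(f"env_link loading {a} outside [-1, 1]")

    @property
    def n_samples(self) -> int:
        return 2 * self.plots_per_habitat * sum(
            len(self.habitats_per_locality[loc]) for loc in self.localities
        )


@dataclass
class GroundTruth:
    """Exactly the planted associations, keyed by final OTU/row ids."""

    positive_pairs: set[tuple[str, str]]
    negative_pairs: set[tuple[str, str]]
    env_pairs: set[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if self.positive_pairs & self.negative_pairs:
            raise ValidationError("planted positive and negative pair sets overlap")


@dataclass
class SyntheticData:
    tables: list[CountTable]
    frame: SampleFrame
    taxonomy: TaxonomyTable
    traits: TraitTable
    truth: GroundTruth
    latent_ids: list[str]
    latent: np.ndarray  # log-abundance matrix [otu, sample], pre-masking


def _pick(rng: np.random.Generator, mix: dict[str, float]) -> str:
    names = sorted(mix)
    probs = np.array([mix[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


def _lognormal_depth(rng: np.random.Generator, mean: float, cv: float) -> int:
    if cv == 0:
        return max(1, int(round(mean)))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return max(1, int(round(rng.lognormal(mu, math.sqrt(sigma2)))))


def _sample_frame(spec: SyntheticSpec, rng: np.random.Generator) -> SampleFrame:
    rows = []
    for loc in spec.localities:
        for hab in spec.habitats_per_locality[loc]:
            base = _SOIL_BASE[hab]
            for p in range(1, spec.plots_per_habitat + 1):
                plot = f"{loc}-{hab}-p{p:02d}"
                # plot-level soil chemistry, shared by the two substrates
                soil = {
                    "pH": base["pH"] + rng.normal(0, 0.25),
                    "C": max(0.1, base["C"] * math.exp(rng.normal(0, 0.3))),
                    "P": max(0.2, base["P"] * math.exp(rng.normal(0, 0.3))),
                    "texture": min(95.0, max(1.0, base["texture"]
                                             + rng.normal(0, 5.0))),
                }
                for cat in ("Na", "K", "Ca", "Mg", "Al", "H_Al"):
                    soil[cat] = base[cat] * math.exp(rng.normal(0, 0.3))
                for sub in ("litter", "soil"):
                    rows.append({
                        "sample_id": f"{plot}-{sub}",
                        "plot_id": plot,
                        "locality": loc,
                        "habitat": hab,
                        "substrate": sub,
                        **soil,
                    })
    df = pd.DataFrame(rows)
    return SampleFrame(df, [c for c in df.columns
                            if c not in ("sample_id", "plot_id", "locality",
                                         "habitat", "substrate")])


def _derive_soil(frame: SampleFrame) -> None:
    """Add the pedological summary indices derived from base cations."""
    d = frame.data
    d["SB"] = d["Ca"] + d["Mg"] + d["K"] + d["Na"]
    d["t"] = d["SB"] + d["Al"]
    d["T"] = d["SB"] + d["H_Al"]
    d["V"] = 100.0 * d["SB"] / d["T"]
    d["m"] = 100.0 * d["Al"] / d["t"]
    for v in ("SB", "t", "T", "V", "m"):
        if v not in frame.soil_vars:
            frame.soil_vars.append(v)


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one synthetic study from ``spec`` (deterministic in ``spec.seed``)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    marker_ids = [m.marker_id for m in spec.markers]

    frame = _sample_frame(spec, rng)
    n_samples = len(frame.sample_ids)
    plots = frame.data["plot_id"].to_numpy()

    # --- assign OTUs ------------------------------------------------------
    otu_ids: list[str] = []
    otu_marker: list[str] = []
    otu_group: list[str] = []
    module_members: list[list[int]] = []
    uniform_markers = {m: 1.0 / len(marker_ids) for m in marker_ids}

    for k, mod in enumerate(spec.modules):
        members = []
        mmix = mod.marker_mix or uniform_markers
        gmix = mod.group_mix or _DEFAULT_GROUP_MIX
        for i in range(mod.size):
            marker = _pick(rng, mmix)
            members.append(len(otu_ids))
            otu_ids.append(f"{marker}_m{k:02d}_{i:02d}")
            otu_marker.append(marker)
            otu_group.append(_pick(rng, gmix))
        module_members.append(members)

    exclusion_members: list[tuple[int, int]] = []
    for j in range(spec.n_exclusion_pairs):
        marker = marker_ids[j % len(marker_ids)]
        a, b = len(otu_ids), len(otu_ids) + 1
        for tag in ("a", "b"):
            otu_ids.append(f"{marker}_x{j:02d}{tag}")
            otu_marker.append(marker)
            otu_group.append(_pick(rng, _DEFAULT_GROUP_MIX))
        exclusion_members.append((a, b))

    background_idx: list[int] = []
    for marker in marker_ids:
        for i in range(spec.n_background_otus):
            background_idx.append(len(otu_ids))
            otu_ids.append(f"{marker}_b{i:04d}")
            otu_marker.append(marker)
            otu_group.append(_pick(rng, _DEFAULT_GROUP_MIX))

    n_otus = len(otu_ids)

    # --- latent log-abundances -------------------------------------------
    mu = rng.normal(0.0, spec.mu_sd, size=n_otus)
    lam = mu[:, None] + np.zeros((n_otus, n_samples))
    module_factors = rng.standard_normal((len(spec.modules), n_samples))
    for k, mod in enumerate(spec.modules):
        idx = module_members[k]
        lam[idx] += mod.loading * module_factors[k][None, :]
        lam[idx] += spec.noise_sd * rng.standard_normal((len(idx), n_samples))
    exclusion_factors = rng.standard_normal((spec.n_exclusion_pairs, n_samples))
    for j, (a, b) in enumerate(exclusion_members):
        lam[a] += spec.exclusion_loading * exclusion_factors[j]
        lam[b] -= spec.exclusion_loading * exclusion_factors[j]
        lam[[a, b]] += spec.noise_sd * rng.standard_normal((2, n_samples))
    if background_idx:
        # background variance matched to the planted rows' total variance
        bg_sd = math.hypot(0.9, spec.noise_sd)
        lam[background_idx] += bg_sd * rng.standard_normal(
            (len(background_idx), n_samples))
    latent = lam.copy()

    # --- rare-OTU masking (background only) -------------------------------
    mask = np.ones((n_otus, n_samples), dtype=bool)
    n_rare = min(len(background_idx), int(round(spec.rare_fraction * n_otus)))
    if n_rare:
        rare = rng.choice(np.array(background_idx), size=n_rare, replace=False)
        unique_plots = sorted(set(plots))
        for o in rare:
            k_plots = int(rng.integers(1, 3))  # present in 1 or 2 plots
            keep = set(rng.choice(unique_plots, size=k_plots, replace=False))
            mask[o] = np.isin(plots, list(keep))

    # --- environmental links ---------------------------------------------
    _derive_soil(frame)
    for k, var, alpha in spec.env_link:
        if var not in frame.soil_vars:
            raise ValidationError(f"env_link names unknown soil variable {var!r}")
        col = frame.data[var].to_numpy(dtype=float)
        scale = float(np.std(col)) or 1.0
        frame.data[var] = col + alpha * scale * module_factors[k]

    # --- counts -----------------------------------------------------------
    weights = np.exp(lam) * mask
    tables: list[CountTable] = []
    for ms in spec.markers:
        rows = [i for i in range(n_otus) if otu_marker[i] == ms.marker_id]
        w = weights[rows]
        counts = np.zeros((len(rows), n_samples))
        for s in range(n_samples):
            tot = w[:, s].sum()
            if tot <= 0:
                continue
            depth = _lognormal_depth(rng, ms.mean_depth, ms.depth_cv)
            counts[:, s] = rng.multinomial(depth, w[:, s] / tot)
        tables.append(CountTable(ms.marker_id, [otu_ids[i] for i in rows],
                                 frame.sample_ids, counts))

    # --- annotations and ground truth ------------------------------------
    tax: dict[str, tuple[str, str, str]] = {}
    traits: dict[str, str] = {}
    for i, otu in enumerate(otu_ids):
        group = otu_group[i]
        phylum = str(rng.choice(_PHYLA[group]))
        cls = f"{phylum}_c{int(rng.integers(1, 4))}" if phylum else ""
        tax[otu] = (group, phylum, cls)
        traits[otu] = str(rng.choice(_TRAITS[group]))

    positive = {
        tuple(sorted((otu_ids[a], otu_ids[b])))
        for members in module_members
        for ai, a in enumerate(members)
        for b in members[ai + 1:]
    }
    negative = {tuple(sorted((otu_ids[a], otu_ids[b])))
                for a, b in exclusion_members}
    env_pairs = {
        (otu_ids[o], var, "pos" if alpha > 0 else "neg")
        for k, var, alpha in spec.env_link
        for o in module_members[k]
        if alpha != 0
    }

    return SyntheticData(
        tables=tables,
        frame=frame,
        taxonomy=TaxonomyTable(tax),
        traits=TraitTable(traits),
        truth=GroundTruth(positive, negative, env_pairs),
        latent_ids=list(otu_ids),
        latent=latent,
    )


def generate_null(n_otus: int, n_samples: int, depth: int, seed: int) -> CountTable:
    """A table with no planted correlation: independent multinomial sampling
    over fixed log-normal per-OTU weights."""
    if min(n_otus, n_samples, depth) <= 0:
        raise ValidationError("n_otus, n_samples and depth must all be positive")
    rng = np.random.default_rng(seed)
    w = rng.lognormal(0.0, 1.0, size=n_otus)
    p = w / w.sum()
    counts = np.column_stack(
        [rng.multinomial(depth, p) for _ in range(n_samples)]
    ).astype(float)
    otus = [f"OTU_{i:04d}" for i in range(n_otus)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    return CountTable("null", otus, samples, counts)


def study_spec(seed: int = 0) -> SyntheticSpec:
    """The full survey emulation: 39 plots x 2 substrates = 78 samples over
    4 localities, habitats present where the field design had them, and three
    markers of decreasing depth."""
    habitats = {
        "BC": ["terra-firme", "varzea", "igapo"],
        "JAU": ["terra-firme", "campina", "igapo"],
        "CUI": ["terra-firme", "campina", "igapo"],
        "CXN": ["terra-firme", "campina", "varzea", "igapo"],
    }
    return SyntheticSpec(
        localities=["BC", "JAU", "CUI", "CXN"],
        habitats_per_locality=habitats,
        plots_per_habitat=3,
        markers=[MarkerSpec("16S", 50_000, 0.3),
                 MarkerSpec("18S", 30_000, 0.3),
                 MarkerSpec("COI", 20_000, 0.3)],
        n_background_otus=200,
        modules=[PlantedModule(8, 0.9) for _ in range(10)],
        n_exclusion_pairs=4,
        env_link=[(0, "C", 0.8), (1, "V", -0.7)],
        rare_fraction=0.6,
        seed=seed,
    )


def benchmark_spec(seed: int = 0, n_modules: int = 10, module_size: int = 8,
                   loading: float = 0.9, n_exclusion_pairs: int = 4) -> SyntheticSpec:
    """The planted-recovery benchmark: one marker, 80 samples (4 localities x
    2 habitats x 5 plots x 2 substrates), 120 background OTUs."""
    habitats = {loc: ["terra-firme", "igapo"] for loc in ("BC", "JAU", "CUI", "CXN")}
    return SyntheticSpec(
        localities=["BC", "JAU", "CUI", "CXN"],
        habitats_per_locality=habitats,
        plots_per_habitat=5,
        markers=[MarkerSpec("16S", 20_000, 0.3)],
        n_background_otus=120,
        modules=[PlantedModule(module_size, loading) for _ in range(n_modules)],
        n_exclusion_pairs=n_exclusion_pairs,
        rare_fraction=0.25,
        seed=seed,
    )
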