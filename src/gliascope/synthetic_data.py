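"""Synthetic probe-level microarray data with planted ground truth.

Emulates the study designs this package analyzes:

* per-gene expression profiles over five CNS cell types, a configurable
  fraction of genes planted as *cell-type enriched* (one type at a fixed
  multiple of the maximum of the others),
* mixed-tissue spinal-cord samples whose per-gene abundance is the
  composition-weighted mixture of the cell-type profiles, with disease
  fold changes applied per cell type and a composition shift emulating
  motor-neuron loss and glial activation,
* isolated single-cell-type samples with a cross-cell-type contamination
  fraction (the laser-capture-microdissection caveat), including planted
  ectopic inductions,
* probe-level intensities: PM = abundance x frozen per-probe affinity x
  multiplicative log-normal noise + additive exponential background, and
  MM = a cross-hybridization fraction of the PM-specific part + its own
  background draw.

Every generator is bit-reproducible given its seed; all sub-streams are
spawned from one master ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .celltypes import CELL_TYPES, UNCLASSIFIED

__all__ = [
    "NoiseParams",
    "CompositionVector",
    "DiseaseEffect",
    "CellTypeProfiles",
    "ChipLayout",
    "SimulatedDataset",
    "SyntheticTruth",
    "CONTROL_COMPOSITION",
    "GLIOSIS_COMPOSITION",
    "validate_disease_shift",
    "generate_celltype_profiles",
    "make_annotation",
    "make_chip_layout",
    "effects_matrix",
    "validate_effects",
    "expected_mixture_abundance",
    "expected_isolated_abundance",
    "generate_tissue_samples",
    "generate_isolated_celltype_samples",
    "simulate_deg_study",
    "simulate_reference_study",
    "simulate_ectopic_study",
    "make_category_map",
]

_COMPOSITION_TOL = 1e-9


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class NoiseParams:
    """Probe-level noise: multiplicative log-normal with coefficient of
    variation ``cv`` (mean one) and additive background with exponential
    mean ``background`` (arbitrary intensity units)."""

    cv: float = 0.15
    background: float = 50.0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.background < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class CompositionVector:
    """Cell-type fractions of a tissue sample under one condition."""

    weights: Mapping[str, float]
    condition: str = "control"

    def __post_init__(self) -> None:
        if set(self.weights) != set(CELL_TYPES):
            raise ValueError(f"composition must cover exactly {CELL_TYPES}")
        w = np.array([self.weights[t] for t in CELL_TYPES], dtype=float)
        if np.any(w < 0):
            raise ValueError("composition weights must be non-negative")
        if abs(w.sum() - 1.0) > _COMPOSITION_TOL:
            raise ValueError(f"composition weights sum to {w.sum()!r}, not 1")
        if self.condition not in ("control", "disease"):
            raise ValueError("condition must be 'control' or 'disease'")
        object.__setattr__(self, "weights", dict(self.weights))

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[t] for t in CELL_TYPES], dtype=float)


#: Plausible healthy lumbar spinal-cord composition: motor neurons are a
#: small minority; glia dominate.
CONTROL_COMPOSITION = CompositionVector(
    {"motor_neuron": 0.06, "neuron": 0.30, "astrocyte": 0.28,
     "microglia": 0.10, "oligodendrocyte": 0.26}, "control")

#: Symptomatic-stage composition: motor-neuron loss with astro- and
#: microgliosis.
GLIOSIS_COMPOSITION = CompositionVector(
    {"motor_neuron": 0.02, "neuron": 0.27, "astrocyte": 0.35,
     "microglia": 0.18, "oligodendrocyte": 0.18}, "disease")


def validate_disease_shift(control: CompositionVector,
                           disease: CompositionVector) -> None:
    """A disease composition must lose motor neurons and gain astrocytes
    and microglia relative to its control."""
    if control.condition != "control" or disease.condition != "disease":
        raise ValueError("expected a (control, disease) composition pair")
    if not (disease.weights["motor_neuron"] < control.weights["motor_neuron"]
            and disease.weights["astrocyte"] > control.weights["astrocyte"]
            and disease.weights["microglia"] > control.weights["microglia"]):
        raise ValueError("disease composition must decrease motor_neuron and "
                         "increase astrocyte and microglia weights")


@dataclass(frozen=True)
class DiseaseEffect:
    """Multiplicative disease fold change of one gene in one cell type.

    ``ectopic`` marks an induction in a cell type other than the gene's
    healthy enrichment class.
    """

    gene_id: str
    cell_type: str
    fold_change: float
    ectopic: bool = False

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if not self.fold_change > 0:
            raise ValueError("fold_change must be positive")


@dataclass
class CellTypeProfiles:
    """Linear-scale base expression of every gene in every cell type plus
    the planted enrichment class."""

    expression: pd.DataFrame
    planted_class: pd.Series

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(CELL_TYPES):
            raise ValueError(f"profile columns must be {CELL_TYPES}")
        if (self.expression.to_numpy() <= 0).any():
            raise ValueError("base expression must be positive for every gene")
        if not self.planted_class.index.equals(self.expression.index):
            raise ValueError("planted_class must align with expression")

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)


@dataclass
class ChipLayout:
    """Probe-to-probeset map with the frozen per-pair probe affinities."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "probeset_id", "pair_index", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout is missing columns: {sorted(missing)}")
        if "affinity" not in self.table.columns:
            self.table = self.table.assign(affinity=1.0)

    @property
    def probesets(self) -> list[str]:
        return list(pd.unique(self.table["probeset_id"]))


@dataclass
class SimulatedDataset:
    """One simulated probe-level dataset plus its chip description."""

    intensities: pd.DataFrame
    layout: ChipLayout
    annotation: pd.DataFrame
    condition: str


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulation — the oracle downstream
    recovery is judged against."""

    seed: int
    planted_deg_genes: frozenset = frozenset()
    planted_class: dict = field(default_factory=dict)
    planted_ectopic: frozenset = frozenset()
    compositions: dict = field(default_factory=dict)
    noise: NoiseParams = NoiseParams()

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "planted_deg_genes": sorted(self.planted_deg_genes),
            "planted_class": dict(sorted(self.planted_class.items())),
            "planted_ectopic": sorted(list(t) for t in self.planted_ectopic),
            "compositions": self.compositions,
            "noise": {"cv": self.noise.cv, "background": self.noise.background},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(seed=d["seed"],
                   planted_deg_genes=frozenset(d["planted_deg_genes"]),
                   planted_class=d["planted_class"],
                   planted_ectopic=frozenset(tuple(t) for t in d["planted_ectopic"]),
                   compositions=d["compositions"],
                   noise=NoiseParams(**d["noise"]))


# ---------------------------------------------------------------------------
# Profiles, annotation, chip
# ---------------------------------------------------------------------------

def _allocate_counts(n: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items over CELL_TYPES."""
    w = np.array([max(0.0, weights.get(t, 0.0)) for t in CELL_TYPES], dtype=float)
    if w.sum() <= 0:
        raise ValueError("class weights must have positive mass")
    raw = w / w.sum() * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts), kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(CELL_TYPES, counts.tolist()))


def generate_celltype_profiles(n_genes: int, enriched_fraction: float = 0.2,
                               enrichment_factor: float = 5.0, seed=0,
                               base_median: float = 200.0,
                               base_sigma: float = 1.0,
                               class_weights: Mapping[str, float] | None = None,
                               ) -> CellTypeProfiles:
    """Plant cell-type-enriched genes among a log-normal gene universe.

    Exactly ``round(enriched_fraction * n_genes)`` genes get one cell type
    at ``enrichment_factor`` times the maximum of the other four; all
    remaining genes have per-type ratios below 4 (multipliers drawn from
    U[1, 1.9]) and are planted Unclassified.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be at least 10")
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must lie in [0, 1]")
    if enrichment_factor < 1.0:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(_seedseq(seed))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = base_median * np.exp(rng.normal(0.0, base_sigma, n_genes))
    expr = base[:, None] * rng.uniform(1.0, 1.9, (n_genes, len(CELL_TYPES)))
    planted = np.full(n_genes, UNCLASSIFIED, dtype=object)

    n_enriched = int(round(enriched_fraction * n_genes))
    if n_enriched:
        idx = rng.choice(n_genes, size=n_enriched, replace=False)
        weights = dict(class_weights) if class_weights else {t: 1.0 for t in CELL_TYPES}
        counts = _allocate_counts(n_enriched, weights)
        types = np.repeat([t for t in CELL_TYPES], [counts[t] for t in CELL_TYPES])
        rng.shuffle(types)
        for i, t in zip(idx, types):
            j = CELL_TYPES.index(t)
            others = np.delete(expr[i], j)
            expr[i, j] = enrichment_factor * others.max()
            planted[i] = t

    index = pd.Index(genes, name="gene_id")
    return CellTypeProfiles(
        expression=pd.DataFrame(expr, index=index, columns=list(CELL_TYPES)),
        planted_class=pd.Series(planted, index=index, name="planted_class"))


def make_annotation(gene_ids: Sequence[str], duplicate_fraction: float = 0.05,
                    seed=0) -> pd.DataFrame:
    """Probeset -> gene map; a fraction of genes get a second probeset to
    exercise deduplication downstream."""
    if not 0.0 <= duplicate_fraction <= 1.0:
        raise ValueError("duplicate_fraction must lie in [0, 1]")
    rng = np.random.default_rng(_seedseq(seed))
    genes = list(gene_ids)
    probesets = [f"{g}_at" for g in genes]
    owners = list(genes)
    n_dup = int(round(duplicate_fraction * len(genes)))
    if n_dup:
        for i in sorted(rng.choice(len(genes), size=n_dup, replace=False)):
            probesets.append(f"{genes[i]}_b_at")
            owners.append(genes[i])
    ann = pd.DataFrame({"probeset_id": probesets, "gene_id": owners})
    return ann.sort_values("probeset_id", kind="mergesort").reset_index(drop=True)


def make_chip_layout(annotation: pd.DataFrame, probes_per_set: int = 11,
                     seed=0, affinity_sigma: float = 0.3) -> ChipLayout:
    """Chip layout with ``probes_per_set`` PM/MM pairs per probeset and a
    frozen log-normal affinity per pair (shared by the pair's PM and MM)."""
    if not 4 <= probes_per_set <= 20:
        raise ValueError("probes_per_set must lie between 4 and 20")
    rng = np.random.default_rng(_seedseq(seed))
    ps = annotation["probeset_id"].to_numpy()
    n_ps = len(ps)
    aff = np.exp(rng.normal(0.0, affinity_sigma, (n_ps, probes_per_set)))
    ps_col = np.repeat(ps, probes_per_set)
    pair_col = np.tile(np.arange(probes_per_set), n_ps)
    pm_ids = [f"{p}:{j}:PM" for p, j in zip(ps_col, pair_col)]
    mm_ids = [f"{p}:{j}:MM" for p, j in zip(ps_col, pair_col)]
    table = pd.DataFrame({
        "probe_id": pm_ids + mm_ids,
        "probeset_id": np.concatenate([ps_col, ps_col]),
        "pair_index": np.concatenate([pair_col, pair_col]),
        "role": ["PM"] * len(pm_ids) + ["MM"] * len(mm_ids),
        "affinity": np.concatenate([aff.ravel(), aff.ravel()]),
    })
    return ChipLayout(table=table)


# ---------------------------------------------------------------------------
# Abundance arithmetic (the closed-form oracle)
# ---------------------------------------------------------------------------

def effects_matrix(effects: Iterable[DiseaseEffect],
                   gene_index: pd.Index) -> pd.DataFrame:
    """Gene x cell-type fold-change matrix (1 everywhere no effect is
    planted)."""
    fc = pd.DataFrame(1.0, index=gene_index, columns=list(CELL_TYPES))
    seen = set()
    for e in effects:
        key = (e.gene_id, e.cell_type)
        if key in seen:
            raise ValueError(f"duplicate effect for {key}")
        seen.add(key)
        if e.gene_id not in gene_index:
            raise ValueError(f"effect references unknown gene {e.gene_id!r}")
        fc.loc[e.gene_id, e.cell_type] = e.fold_change
    return fc


def validate_effects(effects: Iterable[DiseaseEffect],
                     planted_class: pd.Series) -> None:
    """Ectopic effects must target a cell type other than the gene's
    planted enrichment class."""
    for e in effects:
        if e.ectopic and planted_class.get(e.gene_id) == e.cell_type:
            raise ValueError(
                f"effect on {e.gene_id!r} marked ectopic but its planted class "
                f"is its host cell type {e.cell_type!r}")


def expected_mixture_abundance(profiles: CellTypeProfiles,
                               composition: CompositionVector,
                               effects: Iterable[DiseaseEffect] = (),
                               ) -> pd.Series:
    """Noise-free tissue abundance: sum over cell types of weight x base
    expression x (disease fold change when condition is disease)."""
    e = profiles.expression.to_numpy()
    if composition.condition == "disease":
        e = e * effects_matrix(effects, profiles.expression.index).to_numpy()
    ab = e @ composition.as_array()
    return pd.Series(ab, index=profiles.expression.index, name="abundance")


def expected_isolated_abundance(profiles: CellTypeProfiles,
                                target_cell_type: str,
                                contamination_fraction: float,
                                effects: Iterable[DiseaseEffect] = (),
                                condition: str = "control") -> pd.Series:
    """Noise-free isolated-cell abundance: the target profile diluted with
    a uniform mixture of the other four types; disease effects are applied
    per cell type before mixing."""
    if target_cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {target_cell_type!r}")
    if not 0.0 <= contamination_fraction < 0.5:
        raise ValueError("contamination_fraction must lie in [0, 0.5)")
    e = profiles.expression.to_numpy()
    if condition == "disease":
        e = e * effects_matrix(effects, profiles.expression.index).to_numpy()
    j = CELL_TYPES.index(target_cell_type)
    others = np.delete(e, j, axis=1).mean(axis=1)
    ab = (1.0 - contamination_fraction) * e[:, j] + contamination_fraction * others
    return pd.Series(ab, index=profiles.expression.index, name="abundance")


# ---------------------------------------------------------------------------
# Probe-level sampling
# ---------------------------------------------------------------------------

def _probe_intensities(abundance: pd.Series, layout: ChipLayout,
                       annotation: pd.DataFrame, sample_names: Sequence[str],
                       noise: NoiseParams, cross_hyb: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    gene_of = annotation.set_index("probeset_id")["gene_id"]
    pm_t = layout.table[layout.table["role"] == "PM"]
    genes = gene_of.loc[pm_t["probeset_id"]].to_numpy()
    ab = abundance.loc[genes].to_numpy()
    aff = pm_t["affinity"].to_numpy()
    n_pairs, n_samples = len(pm_t), len(sample_names)

    if noise.cv > 0:
        sigma = np.sqrt(np.log1p(noise.cv ** 2))
        factor = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, (n_pairs, n_samples)))
    else:
        factor = np.ones((n_pairs, n_samples))
    specific = (ab * aff)[:, None] * factor
    if noise.background > 0:
        bg_pm = rng.exponential(noise.background, (n_pairs, n_samples))
        bg_mm = rng.exponential(noise.background, (n_pairs, n_samples))
    else:
        bg_pm = bg_mm = np.zeros((n_pairs, n_samples))
    pm = specific + bg_pm
    mm = cross_hyb * specific + bg_mm

    mm_ids = [f"{p}:{j}:MM" for p, j in
              zip(pm_t["probeset_id"], pm_t["pair_index"])]
    index = pd.Index(list(pm_t["probe_id"]) + mm_ids, name="probe_id")
    return pd.DataFrame(np.vstack([pm, mm]), index=index,
                        columns=list(sample_names))


def _resolve_chip(profiles, layout, annotation, probes_per_set,
                  duplicate_fraction, chip_ss):
    if (layout is None) != (annotation is None):
        raise ValueError("pass layout and annotation together, or neither")
    if layout is None:
        ann_ss, lay_ss = chip_ss.spawn(2)
        annotation = make_annotation(profiles.genes, duplicate_fraction, seed=ann_ss)
        layout = make_chip_layout(annotation, probes_per_set, seed=lay_ss)
    return layout, annotation


def generate_tissue_samples(profiles: CellTypeProfiles,
                            composition: CompositionVector,
                            effects: Iterable[DiseaseEffect] = (),
                            n_replicates: int = 3,
                            noise: NoiseParams = NoiseParams(),
                            probes_per_set: int = 11, seed=0,
                            cross_hyb: float = 0.2,
                            layout: ChipLayout | None = None,
                            annotation: pd.DataFrame | None = None,
                            duplicate_fraction: float = 0.05,
                            sample_prefix: str | None = None) -> SimulatedDataset:
    """Simulate replicate mixed-tissue arrays for one condition.

    Disease effects are applied per cell type before mixing, and only when
    the composition's condition is ``disease``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    effects = tuple(effects)
    ss = _seedseq(seed)
    chip_ss, noise_ss = ss.spawn(2)
    layout, annotation = _resolve_chip(profiles, layout, annotation,
                                       probes_per_set, duplicate_fraction, chip_ss)
    abundance = expected_mixture_abundance(profiles, composition, effects)
    prefix = sample_prefix or composition.condition
    names = [f"{prefix}_{i + 1}" for i in range(n_replicates)]
    rng = np.random.default_rng(noise_ss)
    intensities = _probe_intensities(abundance, layout, annotation, names,
                                     noise, cross_hyb, rng)
    return SimulatedDataset(intensities=intensities, layout=layout,
                            annotation=annotation,
                            condition=composition.condition)


def generate_isolated_celltype_samples(profiles: CellTypeProfiles,
                                       target_cell_type: str,
                                       contamination_fraction: float,
                                       effects: Iterable[DiseaseEffect] = (),
                                       n_replicates: int = 3,
                                       noise: NoiseParams = NoiseParams(),
                                       probes_per_set: int = 11, seed=0,
                                       cross_hyb: float = 0.2,
                                       layout: ChipLayout | None = None,
                                       annotation: pd.DataFrame | None = None,
                                       duplicate_fraction: float = 0.05,
                                       condition: str | None = None,
                                       sample_prefix: str | None = None,
                                       ) -> SimulatedDataset:
    """Simulate replicate isolated-cell arrays with cross-cell-type
    contamination (the target type stays dominant: fraction < 0.5)."""
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    effects = tuple(effects)
    if condition is None:
        condition = "disease" if effects else "control"
    ss = _seedseq(seed)
    chip_ss, noise_ss = ss.spawn(2)
    layout, annotation = _resolve_chip(profiles, layout, annotation,
                                       probes_per_set, duplicate_fraction, chip_ss)
    abundance = expected_isolated_abundance(profiles, target_cell_type,
                                            contamination_fraction, effects,
                                            condition)
    prefix = sample_prefix or f"{target_cell_type}_{condition}"
    names = [f"{prefix}_{i + 1}" for i in range(n_replicates)]
    rng = np.random.default_rng(noise_ss)
    intensities = _probe_intensities(abundance, layout, annotation, names,
                                     noise, cross_hyb, rng)
    return SimulatedDataset(intensities=intensities, layout=layout,
                            annotation=annotation, condition=condition)


# ---------------------------------------------------------------------------
# Study-level scenarios
# ---------------------------------------------------------------------------

#: Class mix of planted DEGs, echoing the biology of symptomatic tissue:
#: most differential genes live in microglia, then astrocytes.
DEFAULT_DEG_CLASS_WEIGHTS = {
    "microglia": 0.55, "astrocyte": 0.20, "motor_neuron": 0.04,
    "neuron": 0.03, "oligodendrocyte": 0.03, UNCLASSIFIED: 0.15,
}


@dataclass
class ComparisonData:
    comparison_id: str
    mutant: SimulatedDataset
    control: SimulatedDataset


@dataclass
class DegStudy:
    comparisons: list[ComparisonData]
    profiles: CellTypeProfiles
    layout: ChipLayout
    annotation: pd.DataFrame
    truth: SyntheticTruth


def _pick_deg_genes(profiles: CellTypeProfiles, n_deg: int,
                    class_weights: Mapping[str, float],
                    rng: np.random.Generator) -> list[str]:
    pools = {c: profiles.planted_class.index[profiles.planted_class == c]
             for c in list(CELL_TYPES) + [UNCLASSIFIED]}
    wanted = {c: 0 for c in pools}
    w = {c: class_weights.get(c, 0.0) for c in pools}
    total = sum(w.values())
    if total <= 0:
        raise ValueError("deg class weights must have positive mass")
    raw = {c: w[c] / total * n_deg for c in pools}
    for c in pools:
        wanted[c] = min(int(np.floor(raw[c])), len(pools[c]))
    # distribute the remainder wherever genes remain, Unclassified first
    order = [UNCLASSIFIED] + list(CELL_TYPES)
    while sum(wanted.values()) < n_deg:
        progress = False
        for c in order:
            if sum(wanted.values()) >= n_deg:
                break
            if wanted[c] < len(pools[c]):
                wanted[c] += 1
                progress = True
        if not progress:
            raise ValueError("not enough genes to plant the requested DEGs")
    chosen: list[str] = []
    for c in pools:
        if wanted[c]:
            chosen.extend(rng.choice(pools[c], size=wanted[c], replace=False))
    return sorted(chosen)


def simulate_deg_study(n_genes: int = 10000, n_deg: int = 200,
                       min_fc: float = 2.5, max_fc: float = 6.0,
                       n_comparisons: int = 3, n_replicates: int = 3,
                       noise: NoiseParams = NoiseParams(cv=0.15, background=50.0),
                       probes_per_set: int = 11,
                       enriched_fraction: float = 0.2,
                       enrichment_factor: float = 5.0,
                       deg_class_weights: Mapping[str, float] | None = None,
                       duplicate_fraction: float = 0.05,
                       seed: int = 0) -> DegStudy:
    """The multi-comparison tissue design: ``n_comparisons`` independent
    mutant-vs-control experiments on a shared chip, each mutant group
    carrying the same planted gene-level fold changes.

    Planted effects are applied uniformly across cell types so the planted
    tissue-level fold change equals the planted factor; both conditions
    share the control composition, so differential signal comes only from
    the planted effects.  Effect magnitudes are two-sided, log-uniform in
    ``[min_fc, max_fc]``.
    """
    if n_comparisons < 2:
        raise ValueError("need at least two comparisons to intersect")
    if min_fc <= 1.0 or max_fc < min_fc:
        raise ValueError("require 1 < min_fc <= max_fc")
    ss = np.random.SeedSequence(seed)
    subs = ss.spawn(4 + 2 * n_comparisons)
    profiles = generate_celltype_profiles(
        n_genes, enriched_fraction, enrichment_factor, seed=subs[0])
    annotation = make_annotation(profiles.genes, duplicate_fraction, seed=subs[1])
    layout = make_chip_layout(annotation, probes_per_set, seed=subs[2])
    rng = np.random.default_rng(subs[3])

    deg_genes = _pick_deg_genes(
        profiles, n_deg, deg_class_weights or DEFAULT_DEG_CLASS_WEIGHTS, rng) \
        if n_deg else []
    log_fc = rng.uniform(np.log2(min_fc), np.log2(max_fc), len(deg_genes))
    sign = rng.choice([-1.0, 1.0], size=len(deg_genes))
    effects = [DiseaseEffect(g, t, float(2.0 ** (s * lf)))
               for g, lf, s in zip(deg_genes, log_fc, sign)
               for t in CELL_TYPES]

    control_comp = CONTROL_COMPOSITION
    disease_comp = CompositionVector(dict(control_comp.weights), "disease")
    comparisons = []
    for i in range(n_comparisons):
        cid = f"comparison_{i + 1}"
        mutant = generate_tissue_samples(
            profiles, disease_comp, effects, n_replicates, noise,
            seed=subs[4 + 2 * i], cross_hyb=0.2, layout=layout,
            annotation=annotation, sample_prefix=f"c{i + 1}_mut")
        control = generate_tissue_samples(
            profiles, control_comp, (), n_replicates, noise,
            seed=subs[5 + 2 * i], cross_hyb=0.2, layout=layout,
            annotation=annotation, sample_prefix=f"c{i + 1}_ctl")
        comparisons.append(ComparisonData(cid, mutant, control))

    truth = SyntheticTruth(
        seed=seed, planted_deg_genes=frozenset(deg_genes),
        planted_class=profiles.planted_class.to_dict(),
        planted_ectopic=frozenset(),
        compositions={"control": dict(control_comp.weights),
                      "disease": dict(disease_comp.weights)},
        noise=noise)
    return DegStudy(comparisons=comparisons, profiles=profiles, layout=layout,
                    annotation=annotation, truth=truth)


@dataclass
class ReferenceStudy:
    datasets: dict
    profiles: CellTypeProfiles
    layout: ChipLayout
    annotation: pd.DataFrame


def simulate_reference_study(n_genes: int = 3000,
                             enriched_fraction: float = 0.2,
                             enrichment_factor: float = 5.0,
                             n_replicates: int = 3,
                             noise: NoiseParams = NoiseParams(cv=0.1, background=0.0),
                             contamination_fraction: float = 0.0,
                             probes_per_set: int = 11,
                             profiles: CellTypeProfiles | None = None,
                             layout: ChipLayout | None = None,
                             annotation: pd.DataFrame | None = None,
                             duplicate_fraction: float = 0.05,
                             seed: int = 0) -> ReferenceStudy:
    """Five isolated-cell datasets (one per CNS cell type) on a shared
    chip, for building the integrated reference."""
    ss = np.random.SeedSequence(seed)
    subs = ss.spawn(3 + len(CELL_TYPES))
    if profiles is None:
        profiles = generate_celltype_profiles(
            n_genes, enriched_fraction, enrichment_factor, seed=subs[0])
    if annotation is None:
        annotation = make_annotation(profiles.genes, duplicate_fraction,
                                     seed=subs[1])
    if layout is None:
        layout = make_chip_layout(annotation, probes_per_set, seed=subs[2])
    datasets = {}
    for k, t in enumerate(CELL_TYPES):
        datasets[t] = generate_isolated_celltype_samples(
            profiles, t, contamination_fraction, (), n_replicates, noise,
            seed=subs[3 + k], layout=layout, annotation=annotation,
            sample_prefix=t)
    return ReferenceStudy(datasets=datasets, profiles=profiles, layout=layout,
                          annotation=annotation)


@dataclass
class EctopicStudy:
    control: SimulatedDataset
    disease: SimulatedDataset
    profiles: CellTypeProfiles
    layout: ChipLayout
    annotation: pd.DataFrame
    host: str
    home: str
    marker_genes: tuple
    pure_genes: tuple
    ectopic_gene: str
    effects: tuple
    truth: SyntheticTruth


def simulate_ectopic_study(n_genes: int = 1500, n_pure: int = 500,
                           ectopic_fold: float = 50.0,
                           contamination_fraction: float = 0.1,
                           marker_folds: Sequence[float] = (0.6, 3.1, 8.5),
                           pure_fold_range: tuple[float, float] = (0.5, 8.5),
                           host: str = "astrocyte", home: str = "microglia",
                           n_replicates: int = 3,
                           noise: NoiseParams = NoiseParams(cv=0.15, background=50.0),
                           probes_per_set: int = 11,
                           enriched_fraction: float = 0.45,
                           seed: int = 0) -> EctopicStudy:
    """Isolated host-cell-type datasets contaminated by other cell types,
    with one gene ectopically induced in the host.

    Marker genes of the gene's home cell type carry their own (purely
    cell-intrinsic) disease fold changes, so any apparent change of a
    home-class gene in the host dataset that contamination alone can
    explain stays inside the marker envelope; only the planted ectopic
    induction should escape it.
    """
    if host == home:
        raise ValueError("host and home cell types must differ")
    ss = np.random.SeedSequence(seed)
    subs = ss.spawn(5)
    # weight enrichment toward the home type so enough pure genes exist
    weights = {t: 0.05 for t in CELL_TYPES}
    weights[home] = 0.8
    profiles = generate_celltype_profiles(
        n_genes, enriched_fraction, 5.0, seed=subs[0], class_weights=weights)
    annotation = make_annotation(profiles.genes, 0.0, seed=subs[1])
    layout = make_chip_layout(annotation, probes_per_set, seed=subs[2])
    rng = np.random.default_rng(subs[3])

    home_genes = profiles.planted_class.index[
        profiles.planted_class == home].to_numpy()
    needed = n_pure + len(marker_folds) + 1
    if len(home_genes) < needed:
        raise ValueError(
            f"only {len(home_genes)} {home}-class genes planted; need {needed}")
    picked = rng.choice(home_genes, size=needed, replace=False)
    markers = tuple(sorted(picked[: len(marker_folds)]))
    ectopic_gene = str(picked[len(marker_folds)])
    pure = tuple(sorted(picked[len(marker_folds) + 1:]))

    effects = [DiseaseEffect(g, home, float(f))
               for g, f in zip(markers, marker_folds)]
    effects += [DiseaseEffect(g, home, float(f)) for g, f in
                zip(pure, rng.uniform(*pure_fold_range, size=len(pure)))]
    effects.append(DiseaseEffect(ectopic_gene, home, 10.0))
    effects.append(DiseaseEffect(ectopic_gene, host, ectopic_fold, ectopic=True))
    validate_effects(effects, profiles.planted_class)

    ctl_ss, dis_ss = subs[4].spawn(2)
    control = generate_isolated_celltype_samples(
        profiles, host, contamination_fraction, (), n_replicates, noise,
        seed=ctl_ss, layout=layout, annotation=annotation,
        sample_prefix=f"{host}_ctl", condition="control")
    disease = generate_isolated_celltype_samples(
        profiles, host, contamination_fraction, effects, n_replicates, noise,
        seed=dis_ss, layout=layout, annotation=annotation,
        sample_prefix=f"{host}_dis", condition="disease")

    truth = SyntheticTruth(
        seed=seed, planted_deg_genes=frozenset(),
        planted_class=profiles.planted_class.to_dict(),
        planted_ectopic=frozenset({(ectopic_gene, host)}),
        compositions={}, noise=noise)
    return EctopicStudy(control=control, disease=disease, profiles=profiles,
                        layout=layout, annotation=annotation, host=host,
                        home=home, marker_genes=markers, pure_genes=pure,
                        ectopic_gene=ectopic_gene, effects=tuple(effects),
                        truth=truth)


def make_category_map(planted_class: pd.Series, seed=0,
                      n_random_categories: int = 2,
                      random_fraction: float = 0.1) -> pd.DataFrame:
    """Gene -> category annotation for over-representation analysis: one
    category per planted cell-type program plus random control categories
    (categories may overlap)."""
    rng = np.random.default_rng(_seedseq(seed))
    rows = []
    for c in CELL_TYPES:
        for g in planted_class.index[planted_class == c]:
            rows.append((g, f"{c}_program"))
    n = len(planted_class)
    size = max(1, int(round(random_fraction * n)))
    for k in range(n_random_categories):
        for g in planted_class.index[rng.choice(n, size=size, replace=False)]:
            rows.append((g, f"random_set_{k + 1}"))
    return pd.DataFrame(rows, columns=["gene_id", "category"])
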