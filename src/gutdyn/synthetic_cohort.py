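"""Longitudinal synthetic cohort generator.

Emulates a voluntary oral-morphine self-administration study: ~16 mice in
two outcome groups (non-tolerant / tolerant) sampled weekly over ~22
weeks across five drug-experience phases, ~165 genus-level taxa with
archetype-driven effects, Dirichlet-multinomial counts, a random
coalescent phylogeny, behavioral outputs, and butyrate-pathway gene copy
numbers. Every injected effect is listed in a truth record so downstream
analyses can be validated by recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from gutdyn.tables_io import CountTable, SampleMetadata, RANKS

ARCHETYPES = (
    "depleted_mutualist",
    "enriched_pathobiont",
    "nontolerant_protective",
    "tolerant_marker",
    "neutral",
)

# deterministic per-component seed offsets from the global seed
_SEED_OFFSETS = {
    "composition": 1,
    "depths": 2,
    "tree": 3,
    "behavior": 4,
    "copy_numbers": 5,
    "baseline_shift": 6,
}


def default_phase_boundaries(weeks=None) -> dict[int, str]:
    """Phase schedule: pre 0-1, early 2-6, mid 7-12, late 13-19, post 20+."""
    weeks = list(range(22)) if weeks is None else list(weeks)
    out = {}
    for w in weeks:
        if w <= 1:
            out[w] = "pre"
        elif w <= 6:
            out[w] = "early"
        elif w <= 12:
            out[w] = "mid"
        elif w <= 19:
            out[w] = "late"
        else:
            out[w] = "post"
    return out


@dataclass
class SimConfig:
    """Generative parameters for one synthetic cohort."""

    n_mice_tolerant: int = 10
    n_mice_nontolerant: int = 6
    n_taxa: int = 165
    weeks: list[int] = field(default_factory=lambda: list(range(22)))
    phase_boundaries: dict[int, str] = None
    depth_mean: float = 20_000.0
    depth_dispersion: float = 0.25
    concentration: float = 50.0
    # per-archetype log-abundance drift per morphine week
    dysbiosis_rates: dict[str, float] = field(default_factory=lambda: {
        "depleted_mutualist": -0.18,
        "enriched_pathobiont": 0.40,
        "nontolerant_protective": 0.0,
        "tolerant_marker": 0.0,
        "neutral": 0.0,
    })
    tolerant_variance_inflation: float = 2.0
    changepoint_week_tolerant: int = 5
    changepoint_week_nontolerant: int = 9
    butyrate_effect: float = 0.3
    seed: int = 0
    # secondary knobs (documented defaults; zero/neutral values give a null)
    group_effect: float = 3.0
    diversity_drop: float = 0.25
    noise_sd: float = 0.25
    mouse_sd: float = 0.35
    taxa_seed: int = 42
    baseline_shift_sd: float = 0.0
    cohort: str = "main"
    batch_count: int = 2

    def __post_init__(self) -> None:
        if self.phase_boundaries is None:
            self.phase_boundaries = default_phase_boundaries(self.weeks)
        for name in ("n_mice_tolerant", "n_mice_nontolerant", "n_taxa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.tolerant_variance_inflation < 1:
            raise ValueError("tolerant_variance_inflation must be >= 1")
        missing = [w for w in self.weeks if w not in self.phase_boundaries]
        if missing:
            raise ValueError(f"weeks without phase label: {missing}")


def null_config(**overrides) -> SimConfig:
    """Config with every injected effect switched off (null model)."""
    base = dict(
        dysbiosis_rates={a: 0.0 for a in ARCHETYPES},
        tolerant_variance_inflation=1.0,
        group_effect=0.0,
        diversity_drop=0.0,
        butyrate_effect=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class TaxonArchetype:
    name: str
    baseline_logit_abundance: float
    phase_effects: dict[str, float]
    group_effects: dict[str, float]
    butyrate_producer: bool


def _assign_archetypes(cfg: SimConfig) -> list[TaxonArchetype]:
    """Deterministic taxon panel shared across cohorts (taxa_seed)."""
    rng = np.random.default_rng(cfg.taxa_seed)
    n = cfg.n_taxa
    # fixed proportions, scaled to n_taxa
    quota = {
        "depleted_mutualist": max(1, round(n * 0.15)),
        "enriched_pathobiont": max(1, round(n * 0.09)),
        "nontolerant_protective": max(1, round(n * 0.07)),
        "tolerant_marker": max(1, round(n * 0.05)),
    }
    names = []
    for arch, k in quota.items():
        names += [arch] * k
    names += ["neutral"] * (n - len(names))
    names = names[:n]
    taxa = []
    g = cfg.group_effect
    for i, arch in enumerate(names):
        base = float(rng.normal(0.0, 1.8))
        if arch == "enriched_pathobiont":
            base -= 3.0  # rare pre-morphine so emergence is informative
        elif arch in ("nontolerant_protective", "tolerant_marker"):
            # group-divergent taxa are retained community members, not
            # vanishingly rare ones; keeps their effects identifiable
            base = float(np.clip(base, -1.0, None))
        group_eff = {"tolerant": 0.0, "non_tolerant": 0.0}
        if arch == "nontolerant_protective":
            group_eff["non_tolerant"] = g
        elif arch == "tolerant_marker":
            group_eff["tolerant"] = g
        taxa.append(TaxonArchetype(
            name=arch,
            baseline_logit_abundance=base,
            phase_effects={p: 0.0 for p in SampleMetadata.PHASES},
            group_effects=group_eff,
            butyrate_producer=(
                arch == "nontolerant_protective"
                or (arch == "depleted_mutualist" and rng.random() < 0.4)
            ),
        ))
    return taxa


def _taxon_ids(archetypes: list[TaxonArchetype]) -> list[str]:
    return [f"g{i:03d}_{a.name}" for i, a in enumerate(archetypes)]


def _lineage_for(archetypes: list[TaxonArchetype]) -> dict:
    phyla = ("Bacteroidetes", "Firmicutes", "Proteobacteria",
             "Actinobacteria", "Verrucomicrobia")
    lineage = {}
    for i, (tid, arch) in enumerate(
            zip(_taxon_ids(archetypes), archetypes)):
        lineage[tid] = {r: None for r in RANKS}
        lineage[tid].update({
            "kingdom": "Bacteria",
            "phylum": phyla[i % len(phyla)],
            "family": f"family_{i // 5:03d}",
            "genus": tid,
        })
    return lineage


def _random_coalescent_newick(labels: list[str], rng) -> str:
    """Random bifurcating topology with exponential branch lengths."""
    nodes = [(lab, 0.0) for lab in labels]  # (newick, height)
    height = 0.0
    k = len(nodes)
    while len(nodes) > 1:
        m = len(nodes)
        height += float(rng.exponential(1.0 / m))
        i, j = sorted(rng.choice(m, size=2, replace=False))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        merged = (f"({nwk_i}:{height - h_i:.6f},"
                  f"{nwk_j}:{height - h_j:.6f})")
        nodes.append((merged, height))
    assert k == len(labels)
    return nodes[0][0] + ";"


def _morphine_weeks_elapsed(week: int, phases: dict[int, str]) -> float:
    """Weeks of morphine exposure accumulated by `week` (pre counts 0)."""
    first_morphine = min(
        (w for w, p in phases.items() if p in ("early", "mid", "late")),
        default=None)
    if first_morphine is None or week < first_morphine:
        return 0.0
    last_morphine = max(w for w, p in phases.items()
                        if p in ("early", "mid", "late"))
    return float(min(week, last_morphine) - first_morphine + 1)


def generate_cohort(cfg: SimConfig):
    """Generate one cohort.

    Returns ``(table, metadata, newick, behavior, copy_numbers, truth)``
    where ``behavior`` and ``copy_numbers`` are DataFrames and ``truth``
    records every injected effect.
    """
    archetypes = _assign_archetypes(cfg)
    taxon_ids = _taxon_ids(archetypes)
    n_taxa = cfg.n_taxa

    rng_comp = np.random.default_rng(cfg.seed + _SEED_OFFSETS["composition"])
    rng_depth = np.random.default_rng(cfg.seed + _SEED_OFFSETS["depths"])
    rng_tree = np.random.default_rng(cfg.taxa_seed + _SEED_OFFSETS["tree"])
    rng_beh = np.random.default_rng(cfg.seed + _SEED_OFFSETS["behavior"])
    rng_cn = np.random.default_rng(cfg.seed + _SEED_OFFSETS["copy_numbers"])
    rng_shift = np.random.default_rng(
        cfg.seed + _SEED_OFFSETS["baseline_shift"])

    base = np.array([a.baseline_logit_abundance for a in archetypes])
    if cfg.baseline_shift_sd > 0:
        base = base + rng_shift.normal(0.0, cfg.baseline_shift_sd, n_taxa)
    drift = np.array([cfg.dysbiosis_rates.get(a.name, 0.0)
                      for a in archetypes])

    mice = ([(f"nt{i:02d}", "non_tolerant")
             for i in range(cfg.n_mice_nontolerant)]
            + [(f"t{i:02d}", "tolerant")
               for i in range(cfg.n_mice_tolerant)])

    group_eff = {
        "tolerant": np.array([a.group_effects["tolerant"]
                              for a in archetypes]),
        "non_tolerant": np.array([a.group_effects["non_tolerant"]
                                  for a in archetypes]),
    }
    cp_week = {"tolerant": cfg.changepoint_week_tolerant,
               "non_tolerant": cfg.changepoint_week_nontolerant}

    sample_ids, rows, meta_rows = [], [], []
    for m_idx, (mouse, group) in enumerate(mice):
        mouse_eff = rng_comp.normal(0.0, cfg.mouse_sd, n_taxa)
        for week in cfg.weeks:
            phase = cfg.phase_boundaries[week]
            eta = (base + mouse_eff + group_eff[group]
                   + drift * _morphine_weeks_elapsed(
                       week, cfg.phase_boundaries))
            sd = cfg.noise_sd
            if group == "tolerant" and phase == "mid":
                # the factor scales the latent log-abundance noise;
                # count-level sampling dilutes it, so scaling the sd
                # (not sd^0.5) is what yields a recoverable mid-phase
                # instability signature at the default depth/concentration
                sd *= cfg.tolerant_variance_inflation
            eta = eta + rng_comp.normal(0.0, sd, n_taxa)
            if week >= cp_week[group] and cfg.diversity_drop > 0:
                # sharpen the composition: evenness (Shannon) drops
                eta = eta.mean() + (1.0 + cfg.diversity_drop) * (
                    eta - eta.mean())
            if not np.all(np.isfinite(eta)):
                raise ValueError("non-finite composition "
                                 "(mis-specified effects)")
            p = np.exp(eta - eta.max())
            p /= p.sum()
            q = rng_comp.dirichlet(cfg.concentration * p)
            depth = int(np.round(rng_depth.lognormal(
                np.log(cfg.depth_mean) - cfg.depth_dispersion ** 2 / 2,
                cfg.depth_dispersion)))
            depth = max(depth, 1)
            counts = rng_comp.multinomial(depth, q)
            sid = f"{cfg.cohort}_{mouse}_w{week:02d}"
            sample_ids.append(sid)
            rows.append(counts)
            meta_rows.append(dict(
                sample_id=sid, mouse_id=mouse, week=week, phase=phase,
                tolerance=group, batch=f"run{m_idx % cfg.batch_count}",
                cohort=cfg.cohort,
            ))

    table = CountTable(
        sample_ids=sample_ids,
        taxon_ids=taxon_ids,
        counts=np.array(rows),
        lineage=_lineage_for(archetypes),
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    newick = _random_coalescent_newick(taxon_ids, rng_tree)
    behavior = _generate_behavior(cfg, mice, rng_beh)
    copy_numbers = _generate_copy_numbers(cfg, mice, rng_cn)

    truth = {
        "changepoint_week": dict(cp_week),
        "variance_inflation": {
            "group": "tolerant", "phase": "mid",
            "factor": cfg.tolerant_variance_inflation},
        "dysbiosis_rates": dict(cfg.dysbiosis_rates),
        "group_effect": cfg.group_effect,
        "butyrate_effect": cfg.butyrate_effect,
        "diversity_drop": cfg.diversity_drop,
        "taxa_by_archetype": {
            arch: [t for t, a in zip(taxon_ids, archetypes)
                   if a.name == arch]
            for arch in ARCHETYPES},
        "differential_taxa": [
            t for t, a in zip(taxon_ids, archetypes)
            if a.name in ("nontolerant_protective", "tolerant_marker")],
        "butyrate_producers": [
            t for t, a in zip(taxon_ids, archetypes) if a.butyrate_producer],
        "config": {k: v for k, v in asdict(cfg).items()
                   if k != "phase_boundaries"},
    }
    return table, metadata, newick, behavior, copy_numbers, truth


def _generate_behavior(cfg: SimConfig, mice, rng) -> pd.DataFrame:
    """Per-mouse tail-flick and consumption outputs.

    Non-tolerant mice end at the assay cutoff (100% MPE); tolerant mice
    end below it. Consumption is drawn independently of outcome.
    """
    cutoff = 6.0
    rows = []
    for mouse, group in mice:
        baseline = float(np.clip(rng.normal(2.0, 0.1), 1.5, 2.5))
        if group == "non_tolerant":
            final = cutoff
        else:
            final = float(rng.uniform(baseline + 0.3, cutoff - 0.4))
        rows.append(dict(
            mouse_id=mouse, tolerance=group,
            baseline_latency=round(baseline, 3),
            final_latency=round(final, 3),
            cutoff=cutoff,
            consumption_mg_kg=round(float(np.clip(
                rng.normal(25.0, 10.0), 5.0, 120.0)), 2),
        ))
    return pd.DataFrame(rows)


def _generate_copy_numbers(cfg: SimConfig, mice, rng) -> pd.DataFrame:
    """qPCR copy numbers: butyrate-gene/16S ratio higher in non-tolerant
    mice by exp(butyrate_effect)."""
    rows = []
    for mouse, group in mice:
        s16 = float(rng.lognormal(np.log(1e6), 0.3))
        log_cap = np.log(0.02) + rng.normal(0.0, 0.15)
        if group == "non_tolerant":
            log_cap += cfg.butyrate_effect
        capacity = float(np.exp(log_cap))
        bcoat = 0.6 * capacity * s16
        buk = 0.4 * capacity * s16
        rows.append(dict(
            sample_id=f"{cfg.cohort}_{mouse}_end", mouse_id=mouse,
            tolerance=group, bcoat_copies=bcoat, buk_copies=buk,
            s16_copies=s16,
        ))
    return pd.DataFrame(rows)


def generate_step_series(n: int, change_positions, means, sd: float,
                         seed: int = 0) -> np.ndarray:
    """Piecewise-constant mean Gaussian series (changepoint fixture)."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    positions = list(change_positions)
    if any(not (0 <= p < n) for p in positions):
        raise ValueError("change positions must lie in [0, n)")
    if positions != sorted(set(positions)):
        raise ValueError("change positions must be strictly increasing")
    if len(means) != len(positions) + 1:
        raise ValueError("need one mean per segment")
    rng = np.random.default_rng(seed)
    mu = np.empty(n)
    bounds = [0, *positions, n]
    for seg, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        mu[lo:hi] = means[seg]
    return mu + rng.normal(0.0, sd, n)


def generate_powerlaw_taxa(a: float, b: float, n_taxa: int, n_samples: int,
                           seed: int = 0) -> np.ndarray:
    """Matrix whose per-taxon variance follows V = a * M^b exactly.

    Per-taxon means span >= 3 orders of magnitude; values are drawn
    lognormal with moments matched to (M, V), guaranteeing positivity.
    Returns a (n_samples, n_taxa) array.
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    if n_taxa < 10:
        raise ValueError("need n_taxa >= 10")
    rng = np.random.default_rng(seed)
    M = np.logspace(0.0, 3.5, n_taxa)
    V = a * M ** b
    sigma2 = np.log1p(V / M ** 2)
    mu = np.log(M) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=(n_samples, n_taxa))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_truth(truth: dict, path) -> None:
    """Truth record as key<TAB>value lines (values JSON-encoded)."""
    with open(path, "w") as fh:
        for key, value in truth.items():
            fh.write(f"{key}\t{json.dumps(value)}\n")


def read_truth(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            key, value = line.rstrip("\n").split("\t", 1)
            out[key] = json.loads(value)
    return out
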