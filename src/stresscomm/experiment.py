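"""Factorial experiment pipeline.

Enumerates the full design — total stressor intensity (10%, 50%, 90%,
unfixed) x stressor richness (1..20) x model (three) x initial species
richness (4, 8, 16; the light-spectrum model only at 4) x trait-level
stressor interactions (absent/present) — runs replicate simulations per
cell, and aggregates means with 10th/90th percentile bands.

Each replicate: generate a coexisting community, solve its unstressed
equilibrium, draw an effect matrix (and interaction tensor when
present), rescale to the fixed intensity target when applicable, apply
the stressors to the focal traits, solve and prune the stressed
equilibrium, and record all community metrics plus the stressor
coefficient of variation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import equilibrium, metrics, models, stressors
from .communities import CommunitySpec, SamplingConfig, screen_coexistence, sample_community
from .models import CommunityState

__all__ = [
    "DesignCell",
    "build_design",
    "run_cell",
    "run_replicate",
    "aggregate",
    "TSI_LEVELS",
    "S_VALUES",
    "RICHNESS_LEVELS",
    "METRIC_COLUMNS",
]

TSI_LEVELS = ("10%", "50%", "90%", "unfixed")
S_VALUES = tuple(range(1, 21))
RICHNESS_LEVELS = (4, 8, 16)

METRIC_COLUMNS = (
    "function_ratio", "persistence_fraction", "n_survivors", "bray_curtis",
    "delta_y", "complementarity", "selection",
    "scaled_complementarity", "scaled_selection", "scv", "tsi",
)


@dataclass(frozen=True)
class DesignCell:
    tsi_level: str  # "10%", "50%", "90%" or "unfixed"
    stressor_richness: int
    model: str
    initial_richness: int
    interactions: bool
    replicates: int = 1000
    base_seed: int = 0
    cell_index: int = 0

    def __post_init__(self):
        if self.tsi_level not in TSI_LEVELS:
            raise ValueError(f"tsi_level must be one of {TSI_LEVELS}")
        if self.model == "stomp" and self.initial_richness != 4:
            raise ValueError("the Stomp model runs only at four species")

    @property
    def d(self) -> float | None:
        """Fixed product target d = 1 - TSI, or None when unfixed."""
        if self.tsi_level == "unfixed":
            return None
        return 1.0 - float(self.tsi_level.rstrip("%")) / 100.0

    @property
    def cell_id(self) -> str:
        inter = "eta" if self.interactions else "noeta"
        return (f"{self.model}_n{self.initial_richness}"
                f"_s{self.stressor_richness}_tsi-{self.tsi_level}_{inter}")


def build_design(tsi_levels=TSI_LEVELS, s_values=S_VALUES,
                 model_names=("lotka_volterra", "macarthur", "stomp"),
                 richness_levels=RICHNESS_LEVELS,
                 interaction_levels=(False, True), replicates: int = 1000,
                 base_seed: int = 0, strict: bool = False) -> list[DesignCell]:
    """Cartesian product of factor levels, minus Stomp cells above 4 species.

    With ``strict=True`` an explicitly requested impossible combination
    (Stomp at 8 or 16 species) raises instead of being dropped.
    """
    for name, levels in [("tsi_levels", tsi_levels), ("s_values", s_values),
                         ("model_names", model_names),
                         ("richness_levels", richness_levels),
                         ("interaction_levels", interaction_levels)]:
        if not list(levels):
            raise ValueError(f"{name} must be non-empty")
    cells = []
    for tsi, s, model, n0, inter in itertools.product(
            tsi_levels, s_values, model_names, richness_levels, interaction_levels):
        if model == "stomp" and n0 != 4:
            if strict and set(model_names) == {"stomp"}:
                raise ValueError("Stomp model cannot run at 8 or 16 species")
            continue
        cells.append(DesignCell(
            tsi_level=tsi, stressor_richness=int(s), model=model,
            initial_richness=int(n0), interactions=bool(inter),
            replicates=replicates, base_seed=base_seed, cell_index=len(cells)))
    if not cells:
        raise ValueError("design is empty (only excluded combinations requested)")
    return cells


def _replicate_seed(cell: DesignCell, replicate: int, attempt: int) -> int:
    ss = np.random.SeedSequence(
        [cell.base_seed, cell.cell_index, replicate, attempt])
    return int(ss.generate_state(1)[0] % 2**31)


def run_replicate(cell: DesignCell, seed: int,
                  sampling: SamplingConfig | None = None,
                  threshold_fraction: float = 0.01,
                  community_attempts: int = 2000) -> metrics.MetricRecord:
    """One end-to-end simulation; raises RuntimeError on solver failure."""
    rng = np.random.default_rng(seed)
    spec = CommunitySpec(model=cell.model, n_species=cell.initial_richness,
                         sampling=sampling or SamplingConfig())
    params = unstressed = K = None
    for _ in range(community_attempts):
        cand = sample_community(spec, rng)
        res = screen_coexistence(cand, threshold_fraction)
        if res.accept:
            params, unstressed, K = cand, res.state, res.carrying_capacities
            break
    if params is None:
        raise RuntimeError(f"no coexisting community in {community_attempts} draws")

    n, s = cell.initial_richness, cell.stressor_richness
    E = stressors.sample_effects(n, s, rng)
    eta = stressors.sample_interactions(n, s, rng) if cell.interactions else None
    if cell.d is not None:
        E = stressors.rescale_to_fixed_tsi(E, cell.d)
    theta0 = models.focal_traits(params)
    theta = stressors.apply_stressors(theta0, E, eta)

    report = equilibrium.prune_extinctions(
        params, theta, threshold_fraction,
        carrying_capacities=K, initial_state=unstressed)
    if not report.converged:
        raise RuntimeError("stressed equilibrium did not converge")
    stressed = report.state

    stressed_params = models.with_focal_traits(params, theta)
    mono = models.carrying_capacities(stressed_params)
    bio = _partition(stressed.abundances, mono, n)

    count, frac = metrics.persistence(stressed, unstressed)
    # compositional resistance: Bray-Curtis on relative abundances, so a
    # uniform scaling of the whole community does not read as composition
    # change (all-extinct communities score 0 against any composition)
    total = stressed.abundances.sum()
    rel_stressed = stressed.abundances / total if total > 0 else stressed.abundances
    rel_unstressed = unstressed.abundances / unstressed.abundances.sum()
    return metrics.MetricRecord(
        cell_id=cell.cell_id, replicate=-1, seed=seed,
        function_ratio=metrics.ecosystem_function(stressed, unstressed),
        n_survivors=count, persistence_fraction=frac,
        bray_curtis=metrics.bray_curtis_similarity(rel_stressed, rel_unstressed),
        delta_y=bio.delta_y, complementarity=bio.complementarity,
        selection=bio.selection,
        scaled_complementarity=bio.scaled_complementarity,
        scaled_selection=bio.scaled_selection,
        scv=stressors.stressor_cv(E),
        tsi=stressors.total_stressor_intensity(E),
    )


def _partition(observed: np.ndarray, mono: np.ndarray,
               n: int) -> metrics.BiodiversityEffects:
    """Loreau-Hector partition under stressed monocultures.

    Species whose stressed monoculture equilibrium is zero cannot be
    attributed a relative yield; they are excluded (rare, and only
    possible for the resource/light models).
    """
    ok = mono > 0
    if ok.sum() < 2:
        return metrics.BiodiversityEffects(
            math.nan, math.nan, math.nan, math.nan, math.nan)
    return metrics.biodiversity_effects(observed[ok], mono[ok], 1.0 / n)


def run_cell(cell: DesignCell, sampling: SamplingConfig | None = None,
             threshold_fraction: float = 0.01, replacement_cap: int = 5,
             progress: bool = False) -> pd.DataFrame:
    """All replicates of one design cell as a long-format table.

    Replicates whose solve fails are replaced with a fresh seed (up to
    ``replacement_cap`` attempts each); the replacement count is attached
    as ``DataFrame.attrs['replacements']``.
    """
    records, replacements = [], 0
    reps = range(cell.replicates)
    if progress:
        from tqdm import tqdm
        reps = tqdm(reps, desc=cell.cell_id)
    for rep in reps:
        rec = None
        for attempt in range(replacement_cap):
            seed = _replicate_seed(cell, rep, attempt)
            try:
                rec = run_replicate(cell, seed, sampling, threshold_fraction)
                break
            except RuntimeError:
                replacements += 1
        if rec is None:
            raise RuntimeError(
                f"replicate {rep} of {cell.cell_id} failed "
                f"{replacement_cap} times")
        rec.replicate = rep
        records.append(rec.as_dict())
    df = pd.DataFrame.from_records(records, columns=metrics.MetricRecord.COLUMNS)
    df.insert(1, "tsi_level", cell.tsi_level)
    df.insert(2, "stressor_richness", cell.stressor_richness)
    df.insert(3, "model", cell.model)
    df.insert(4, "initial_richness", cell.initial_richness)
    df.insert(5, "interactions", cell.interactions)
    df.attrs["replacements"] = replacements
    return df


CELL_KEYS = ["cell_id", "tsi_level", "stressor_richness", "model",
             "initial_richness", "interactions"]


def aggregate(records: pd.DataFrame,
              metric_columns=METRIC_COLUMNS) -> pd.DataFrame:
    """Per-cell mean and empirical 10th/90th percentiles per metric.

    NaN metric values (e.g. scaled effects when DeltaY = 0) are excluded;
    ``<metric>_n`` reports how many replicates contributed.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    keys = [k for k in CELL_KEYS if k in records.columns]
    rows = []
    for key_vals, grp in records.groupby(keys, sort=True):
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row["replicates_completed"] = len(grp)
        for col in metric_columns:
            vals = grp[col].dropna().to_numpy(dtype=float)
            row[f"{col}_n"] = vals.size
            if vals.size == 0:
                row[f"{col}_mean"] = row[f"{col}_q10"] = row[f"{col}_q90"] = np.nan
            else:
                row[f"{col}_mean"] = vals.mean()
                row[f"{col}_q10"] = np.percentile(vals, 10)
                row[f"{col}_q90"] = np.percentile(vals, 90)
        rows.append(row)
    return pd.DataFrame(rows)
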