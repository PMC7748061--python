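"""The 25-year wheat breeding program with overlapping cycles.

Every year a new breeding cycle is initiated: 60 parents are crossed into
100 F1 families, which funnel through single-plant visual selection (F2,
F4), family-level yield selection (F3), a preliminary yield trial (F5,
750 -> 150), and two advanced yield trials (F6, 150 -> 30; F7, 30 -> 5),
with the 5 F8 survivors as the cycle's product.  A cycle started in year
``c`` has its generation ``Fg`` grown and acted on in year ``c + g``, so at
steady state nine generations (P through F8) of different cycles run
concurrently and selected F5/F6/F7 lines feed a rolling parent pool.

Two strategies share this structure.  Under phenotypic selection (PS) the
F5/F6/F7 criteria are plot means.  Under genomic selection (GS) the first 8
years are a phenotypic burn-in; from year 9 selected F4 lines are genotyped
(750 per year joining the reference population) and the F5/F6/F7 criteria
become multi-trait GBLUP breeding values (GEBV of PYT at F5, of AYT at F6
and F7).  With a shared seed, PS and GS trajectories are identical through
the burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome, meiosis, traits
from .evaluation import selection_accuracy, solve_multitrait_gblup
from .traits import AYT, BVP, PYT


class FunnelError(RuntimeError):
    pass


class PoolExhaustionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SchemeConfig:
    """All counts and rates of the breeding program (defaults as published)."""

    years: int = 25
    burn_in_years: int = 8
    strategy: str = "PS"              # PS or GS
    corr_pyt_ayt: float = 0.1
    corr_bvp: float = 0.1

    # genome / founders
    n_loci: int = 9582
    n_qtl: int = 1039
    n_chromosomes: int = 21
    map_length_cM: float = 150.0
    n_founders: int = 988
    n_base: int = 480
    marker_thin_step: int | None = None   # scaled-down GS: keep every k-th marker

    # crossing block
    n_parents: int = 60
    n_crosses: int = 100
    max_crosses_per_parent: int = 6

    # stage funnel
    f2_seeds_per_f1: int = 30
    f2_select_per_family: int = 8
    f3_families_kept: int = 75
    f3_plots_per_family: int = 3
    f4_plants_per_family: int = 30
    f4_select_per_family: int = 10
    f5_kept: int = 150
    f6_kept: int = 30
    f7_kept: int = 5

    # trials
    pyt_plot_plants: int = 50
    ayt_plot_plants: int = 1500
    ayt_replicates: int = 9           # 3 plots x 3 locations, no GxE

    # heritabilities
    h2_bvp: float = 0.1
    h2_pyt: float = 0.2
    h2_ayt: float = 0.3

    # phenotype model
    residual_mode: str = "empirical"  # or "analytic" (printed formula)

    # parents
    parent_pool_window: int | None = None  # stored-line years eligible for a
                                           # random draw (None: never retired)
    truncation_window: int = 3             # stored-line years ranked when
                                           # parents are truncation-selected
    parent_selection: str = "auto"    # auto: PS draws randomly from the
                                      # stored pool, GS truncates on stored
                                      # AYT GEBVs after burn-in; or force
                                      # "random" / "truncation"

    # genomic evaluation
    reference_window: int | None = None  # cohorts used in GBLUP (None = all)
    grm_blend: float = 0.01

    def validate(self):
        if self.strategy not in ("PS", "GS"):
            raise ValueError("strategy must be PS or GS")
        if self.burn_in_years >= self.years:
            raise ValueError("burn-in must be shorter than the program")
        if self.f2_select_per_family > self.f2_seeds_per_f1:
            raise FunnelError("cannot select more F2 plants than sown")
        if self.f3_families_kept > self.n_crosses:
            raise FunnelError("cannot keep more families than crosses")
        if self.f4_select_per_family > self.f4_plants_per_family:
            raise FunnelError("cannot select more F4 plants than grown")
        n_f4 = self.f3_families_kept * self.f4_select_per_family
        if not n_f4 >= self.f5_kept >= self.f6_kept >= self.f7_kept:
            raise FunnelError("late-stage funnel counts not nonincreasing")


#: scaled-down genomic-selection mode used for desk-scale replication:
#: marker panel thinned to ~2000 and the GBLUP reference windowed to the
#: three most recent genotyped cohorts.
SCALED_GS_OVERRIDES = dict(strategy="GS", marker_thin_step=4,
                           reference_window=3)


def scaled_gs_config(**kwargs) -> SchemeConfig:
    return SchemeConfig(**{**SCALED_GS_OVERRIDES, **kwargs})


# ---------------------------------------------------------------------------
# crossing-block operations
# ---------------------------------------------------------------------------

def count_possible_crosses(n_parents: int) -> int:
    """Number of unordered parent pairs without selfing."""
    if n_parents < 2:
        raise ValueError("need at least two parents")
    return n_parents * (n_parents - 1) // 2


def make_crosses(n_parents: int, n_crosses: int, max_per_parent: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Sample distinct unordered pairs uniformly, capping parent usage.

    Pairs are drawn uniformly from all ``n_parents choose 2`` and rejected
    if repeated or if either parent already reached ``max_per_parent`` uses.
    """
    if n_crosses > count_possible_crosses(n_parents):
        raise ValueError("more crosses requested than distinct pairs exist")
    if 2 * n_crosses > n_parents * max_per_parent:
        raise ValueError("per-parent cap makes the crossing block infeasible")
    for _ in range(100):  # fresh attempt if rejection sampling stalls
        usage = np.zeros(n_parents, dtype=np.int64)
        chosen: set[tuple[int, int]] = set()
        pairs = []
        stall = 0
        while len(pairs) < n_crosses and stall < 10000:
            i, j = rng.integers(0, n_parents, size=2)
            if i == j:
                continue
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            if (a, b) in chosen or usage[a] >= max_per_parent \
                    or usage[b] >= max_per_parent:
                stall += 1
                continue
            chosen.add((a, b))
            usage[a] += 1
            usage[b] += 1
            pairs.append((a, b))
            stall = 0
        if len(pairs) == n_crosses:
            return np.array(pairs, dtype=np.int64)
    raise RuntimeError("could not assemble a valid crossing block")


# ---------------------------------------------------------------------------
# program state
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """One breeding cycle's current plant material."""

    cycle: int
    stage: str                 # generation grown this year (F1..F8)
    haps: np.ndarray           # (n, 2, L) int8
    ids: np.ndarray            # (n,) global line ids
    family: np.ndarray         # (n,) F1-family index within the cycle
    tbv: np.ndarray            # (n, 3)
    orig_index: np.ndarray     # position within the cycle's 750 F4 lines (-1 before F4)
    carried_accuracy: float = float("nan")  # F7-decision accuracy for F8 report

    @property
    def n(self) -> int:
        return self.haps.shape[0]


@dataclass
class CohortInfo:
    """Persistent per-cycle data for genomic evaluation."""

    cycle: int
    geno: np.ndarray | None = None       # (k, m) marker dosage at genotyping
    geno_orig: np.ndarray | None = None  # (k,) orig_index of genotyped lines
    f4_genotyped: bool = False
    records: list = field(default_factory=list)  # (orig_idx, trait, values, resid_var)


@dataclass
class ParentPool:
    """Rolling pool of stored selected lines plus the base population."""

    base_haps: np.ndarray
    base_tbv: np.ndarray
    entries: list = field(default_factory=list)  # dicts with year/haps/tbv/ids/criterion

    def add(self, year, haps, tbv, ids, criterion, cycle=-1, orig=None):
        self.entries.append(dict(year=year, haps=haps, tbv=tbv, ids=ids,
                                 criterion=criterion, cycle=cycle,
                                 orig=orig))

    def prune(self, year, window):
        if window is not None:
            self.entries = [e for e in self.entries
                            if e["year"] >= year - window]

    def stored(self, year, window):
        lo = -1 if window is None else year - window
        keep = [e for e in self.entries if lo <= e["year"] < year]
        if not keep:
            return None
        return {
            "haps": np.concatenate([e["haps"] for e in keep]),
            "tbv": np.concatenate([e["tbv"] for e in keep]),
            "ids": np.concatenate([e["ids"] for e in keep]),
            "criterion": np.concatenate([e["criterion"] for e in keep]),
        }


def draw_parents(pool: ParentPool, n: int, year: int,
                 rng: np.random.Generator, *, burn_in_source_years: int = 7,
                 window: int | None = None, selection: str = "random"):
    """Select the year's 60 parents.

    Years 1..7 draw uniformly from the 480-line base population; from year 8
    on, uniformly from lines stored at the F5/F6/F7 selections of previous
    years (all of them when ``window`` is None, else the last ``window``
    years).  The pool is elite by construction; the draw itself is random
    unless ``selection="truncation"``.
    Returns ``(haps, tbv, ids)``.
    """
    if year <= burn_in_source_years:
        n_base = pool.base_haps.shape[0]
        if n > n_base:
            raise PoolExhaustionError("base population smaller than parent draw")
        idx = rng.choice(n_base, size=n, replace=False)
        return pool.base_haps[idx], pool.base_tbv[idx], -1 - idx  # base ids < 0
    stored = pool.stored(year, window)
    if stored is None or stored["ids"].size < n:
        raise PoolExhaustionError(
            f"parent pool has fewer than {n} stored lines in year {year}")
    if selection == "truncation":
        crit = np.nan_to_num(stored["criterion"], nan=-np.inf)
        order = np.lexsort((stored["ids"], -crit))
        idx = order[:n]
    else:
        idx = rng.choice(stored["ids"].size, size=n, replace=False)
    return stored["haps"][idx], stored["tbv"][idx], stored["ids"][idx]


@dataclass
class ProgramState:
    year: int
    layout: genome.GenomeLayout
    model: traits.TraitModel
    pool: ParentPool
    marker_freq: np.ndarray
    cohorts: dict = field(default_factory=dict)        # cycle -> Cohort
    cohort_info: dict = field(default_factory=dict)    # cycle -> CohortInfo
    grm_cache: dict = field(default_factory=dict)      # (ca, cb) -> raw block
    zc_cache: dict = field(default_factory=dict)       # cycle -> centred dosage
    next_id: int = 0
    reference_size: int = 0
    stats_rows: list = field(default_factory=list)

    def take_ids(self, n: int) -> np.ndarray:
        ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += n
        return ids


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _top_k(criterion: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k best by criterion; ties broken by line id (stable)."""
    order = np.lexsort((ids, -criterion))
    return order[:k]


def _top_k_within_family(criterion: np.ndarray, n_families: int,
                         fam_size: int, k: int) -> np.ndarray:
    """Top-k per family for contiguous equal-sized family blocks."""
    mat = criterion.reshape(n_families, fam_size)
    picked = np.argsort(-mat, axis=1, kind="stable")[:, :k]
    return (picked + (np.arange(n_families) * fam_size)[:, None]).ravel()


def _stage_stats(state: ProgramState, cohort: Cohort, accuracy: float):
    m = cohort.tbv.mean(axis=0)
    v = cohort.tbv.var(axis=0, ddof=1) if cohort.n > 1 else np.zeros(3)
    state.stats_rows.append(dict(
        year=state.year, cycle=cohort.cycle, stage=cohort.stage, n=cohort.n,
        mean_BVP=m[BVP], mean_PYT=m[PYT], mean_AYT=m[AYT],
        var_BVP=v[BVP], var_PYT=v[PYT], var_AYT=v[AYT],
        accuracy=accuracy, reference_size=state.reference_size))


def _marker_dosage(haps: np.ndarray, layout: genome.GenomeLayout) -> np.ndarray:
    return haps[:, :, layout.marker_idx].sum(axis=1).astype(np.int8)


def _genotype_cohort(state: ProgramState, cohort: Cohort, *, at_f4: bool):
    info = state.cohort_info.setdefault(cohort.cycle, CohortInfo(cohort.cycle))
    if info.geno is not None:
        return
    info.geno = _marker_dosage(cohort.haps, state.layout)
    info.geno_orig = cohort.orig_index.copy()
    info.f4_genotyped = at_f4
    if at_f4:
        state.reference_size += cohort.n


def _append_record(state: ProgramState, cohort: Cohort, trait: int,
                   values: np.ndarray, resid_var: float):
    info = state.cohort_info.setdefault(cohort.cycle, CohortInfo(cohort.cycle))
    info.records.append((cohort.orig_index.copy(), trait,
                         np.asarray(values, dtype=np.float64), resid_var))


def _window_cycles(state: ProgramState, window: int | None) -> list[int]:
    """Genotyped cycles with yield records, most recent first."""
    cycles = [c for c, info in state.cohort_info.items()
              if info.geno is not None and info.records]
    cycles.sort(reverse=True)
    return cycles if window is None else cycles[:window]


def _cohort_zc(state: ProgramState, cycle: int) -> np.ndarray:
    if cycle not in state.zc_cache:
        info = state.cohort_info[cycle]
        state.zc_cache[cycle] = (info.geno.astype(np.float32)
                                 - 2.0 * state.marker_freq.astype(np.float32))
    return state.zc_cache[cycle]


def _solve_gebvs(state: ProgramState, config: SchemeConfig) -> dict:
    """One multi-trait GBLUP solve per year, shared by F5/F6/F7 decisions.

    The line set is the reference window (the most recent genotyped cohorts
    with yield records; all F5/F6/F7 candidates of the year belong to it).
    Returns ``{cycle: (orig_index, gebv (k, 3))}``.
    """
    cycles = _window_cycles(state, config.reference_window)
    if not cycles:
        return {}
    # decision cohorts (the year's F5/F6/F7) must be in the line set even
    # when the reference window is narrower
    decision = {state.year - g for g in (5, 6, 7)}
    extra = [c for c in _window_cycles(state, None)
             if c in decision and c not in cycles]
    cycles = sorted(set(cycles) | set(extra), reverse=True)
    offsets, line_cycle = {}, []
    total = 0
    for c in cycles:
        k = state.cohort_info[c].geno.shape[0]
        offsets[c] = total
        total += k
        line_cycle.append((c, k))

    denom = np.sum(2.0 * state.marker_freq * (1.0 - state.marker_freq))
    G = np.empty((total, total))
    for a in cycles:
        za = _cohort_zc(state, a)
        for b in cycles:
            if b > a:
                continue
            key = (a, b)
            if key not in state.grm_cache:
                zb = _cohort_zc(state, b)
                state.grm_cache[key] = (za @ zb.T).astype(np.float64) / denom
            blk = state.grm_cache[key]
            ra, rb = offsets[a], offsets[b]
            G[ra:ra + blk.shape[0], rb:rb + blk.shape[1]] = blk
            if a != b:
                G[rb:rb + blk.shape[1], ra:ra + blk.shape[0]] = blk.T
    G = (1.0 - config.grm_blend) * G + config.grm_blend * np.eye(total)

    li, ti, yv, rv = [], [], [], []
    for c in cycles:
        info = state.cohort_info[c]
        pos = {int(o): offsets[c] + r for r, o in enumerate(info.geno_orig)}
        for orig_idx, trait, values, resid_var in info.records:
            for o, val in zip(orig_idx, values):
                row = pos.get(int(o))
                if row is not None:
                    li.append(row)
                    ti.append(trait)
                    yv.append(val)
                    rv.append(resid_var)
    result = solve_multitrait_gblup(
        (np.array(li), np.array(ti), np.array(yv), np.array(rv)),
        G, state.model.G0, method="gls")

    out = {"_means": result.means}
    for c in cycles:
        info = state.cohort_info[c]
        rows = offsets[c] + np.arange(info.geno.shape[0])
        out[c] = (info.geno_orig, result.scores[rows])
    return out


def _gebv_for(gebvs: dict, cohort: Cohort, trait: int) -> np.ndarray:
    orig, scores = gebvs[cohort.cycle]
    pos = {int(o): r for r, o in enumerate(orig)}
    rows = np.array([pos[int(o)] for o in cohort.orig_index])
    return scores[rows, trait]


# ---------------------------------------------------------------------------
# one year of the program
# ---------------------------------------------------------------------------

def advance_year(state: ProgramState, config: SchemeConfig,
                 rng: np.random.Generator) -> ProgramState:
    """Execute all stage actions of one year, in place, and return state.

    Phases: (A) all plot/plant phenotypes are simulated (identically under
    PS and GS, so burn-in trajectories are bit-equal under a shared seed);
    (B) yield records are logged and, under GS from year 9, cohorts are
    genotyped; (C) under GS one multi-trait GBLUP solve serves the year's
    decisions; (D) selections and advancement run from oldest to youngest
    cohort, and the new cycle's crossing block is formed.
    """
    state.year += 1
    year = state.year
    model, layout = state.model, state.layout
    gs_active = config.strategy == "GS" and year > config.burn_in_years
    se2 = model.sigma_e2
    rv_pyt = se2["PYT"] / config.pyt_plot_plants
    rv_ayt9 = se2["AYT"] / config.ayt_plot_plants / config.ayt_replicates

    stages = sorted(state.cohorts.items(), key=lambda kv: kv[0])  # old first

    # --- phase A: phenotypes -------------------------------------------------
    pheno: dict[int, np.ndarray] = {}
    for cycle, cohort in stages:
        g = year - cycle
        if g in (2, 4):      # single-plant visual preference
            pheno[cycle] = traits.simulate_plant_phenotype(
                cohort.tbv[:, BVP], model, rng)
        elif g == 3:         # family yield plots, AYT setup
            n_fam = config.n_crosses
            fam_means = np.empty(n_fam)
            members = cohort.tbv[:, AYT].reshape(n_fam, -1)
            se_plot = np.sqrt(se2["AYT"] / config.ayt_plot_plants)
            for f in range(n_fam):
                vals = []
                for _ in range(config.f3_plots_per_family):
                    picks = rng.integers(0, members.shape[1],
                                         size=config.ayt_plot_plants)
                    vals.append(members[f, picks].mean()
                                + rng.normal(0.0, se_plot))
                fam_means[f] = np.mean(vals)
            pheno[cycle] = fam_means
        elif g == 5:         # preliminary yield trial, one 50-plant plot
            pheno[cycle] = traits.plot_values_batch(
                cohort.tbv[:, PYT], "PYT", config.pyt_plot_plants, model, rng)
        elif g in (6, 7):    # advanced yield trial, 9 replicate plots
            y9 = traits.plot_values_batch(
                cohort.tbv[:, AYT], "AYT", config.ayt_plot_plants, model, rng,
                n_replicates=config.ayt_replicates)
            pheno[cycle] = y9.mean(axis=1)

    # --- phase B: records and genotyping ------------------------------------
    for cycle, cohort in stages:
        g = year - cycle
        if g == 5:
            _append_record(state, cohort, PYT, pheno[cycle], rv_pyt)
        elif g in (6, 7):
            _append_record(state, cohort, AYT, pheno[cycle], rv_ayt9)
    if gs_active and year == config.burn_in_years + 1:
        # first GS year: cohorts already past F4 are genotyped at their
        # current stage so GEBV selection can start immediately
        for cycle, cohort in stages:
            if year - cycle in (5, 6, 7):
                _genotype_cohort(state, cohort, at_f4=False)

    # --- phase C: one GBLUP solve for the year's decisions -------------------
    gebvs = _solve_gebvs(state, config) if gs_active else {}

    # --- phase D: selections and advancement (oldest cohort first) ----------
    new_cohorts: dict[int, Cohort] = {}
    pool_additions = []
    for cycle, cohort in stages:
        g = year - cycle
        if g == 8:  # product generation: report and retire
            _stage_stats(state, cohort, cohort.carried_accuracy)
            continue
        if g == 1:
            _stage_stats(state, cohort, float("nan"))
            n_seeds = config.f2_seeds_per_f1
            parent_idx = np.repeat(np.arange(cohort.n), n_seeds)
            kids = meiosis.self_batch(cohort.haps, parent_idx, layout, rng)
            new_cohorts[cycle] = Cohort(
                cycle=cycle, stage="F2", haps=kids,
                ids=state.take_ids(kids.shape[0]),
                family=np.repeat(cohort.family, n_seeds),
                tbv=model.tbv(kids),
                orig_index=np.full(kids.shape[0], -1, dtype=np.int64))
        elif g == 2:
            _stage_stats(state, cohort, float("nan"))
            sel = _top_k_within_family(pheno[cycle], config.n_crosses,
                                       config.f2_seeds_per_f1,
                                       config.f2_select_per_family)
            kids = meiosis.self_batch(cohort.haps, sel, layout, rng)
            new_cohorts[cycle] = Cohort(
                cycle=cycle, stage="F3", haps=kids,
                ids=state.take_ids(kids.shape[0]),
                family=cohort.family[sel], tbv=model.tbv(kids),
                orig_index=np.full(kids.shape[0], -1, dtype=np.int64))
        elif g == 3:
            _stage_stats(state, cohort, float("nan"))
            fam_crit = pheno[cycle]
            fam_ids = np.arange(config.n_crosses)
            keep_fams = np.sort(fam_ids[_top_k(fam_crit, fam_ids,
                                               config.f3_families_kept)])
            fam_size = config.f2_select_per_family
            # each surviving family contributes f4_plants_per_family selfed
            # seeds, allocated round-robin over its plants
            within = np.arange(config.f4_plants_per_family) % fam_size
            parent_idx = (keep_fams[:, None] * fam_size + within[None, :]
                          ).ravel()
            kids = meiosis.self_batch(cohort.haps, parent_idx, layout, rng)
            new_cohorts[cycle] = Cohort(
                cycle=cycle, stage="F4", haps=kids,
                ids=state.take_ids(kids.shape[0]),
                family=np.repeat(keep_fams, config.f4_plants_per_family),
                tbv=model.tbv(kids),
                orig_index=np.full(kids.shape[0], -1, dtype=np.int64))
        elif g == 4:
            _stage_stats(state, cohort, float("nan"))
            sel = _top_k_within_family(pheno[cycle], config.f3_families_kept,
                                       config.f4_plants_per_family,
                                       config.f4_select_per_family)
            selected = Cohort(
                cycle=cycle, stage="F4sel", haps=cohort.haps[sel],
                ids=cohort.ids[sel], family=cohort.family[sel],
                tbv=cohort.tbv[sel],
                orig_index=np.arange(sel.size, dtype=np.int64))
            if gs_active:
                _genotype_cohort(state, selected, at_f4=True)
            kids = meiosis.self_batch(selected.haps,
                                      np.arange(selected.n), layout, rng)
            new_cohorts[cycle] = Cohort(
                cycle=cycle, stage="F5", haps=kids,
                ids=state.take_ids(kids.shape[0]), family=selected.family,
                tbv=model.tbv(kids), orig_index=selected.orig_index)
        elif g in (5, 6, 7):
            n_keep = {5: config.f5_kept, 6: config.f6_kept,
                      7: config.f7_kept}[g]
            crit_trait = PYT if g == 5 else AYT
            if gs_active:
                criterion = _gebv_for(gebvs, cohort, crit_trait)
            else:
                criterion = pheno[cycle]
            if cohort.n < n_keep:
                raise FunnelError(
                    f"year {year} cycle {cycle} F{g}: {cohort.n} candidates "
                    f"for {n_keep} slots")
            acc = selection_accuracy(criterion, cohort.tbv[:, AYT])
            _stage_stats(state, cohort, acc)
            sel = _top_k(criterion, cohort.ids, n_keep)
            # pool criterion: what a later parent choice can rank lines by.
            # Under GS this is the stored AYT GEBV on the absolute scale
            # (fitted trait mean + genomic deviation) so that lines stored
            # in different years remain comparable; otherwise the stage
            # criterion.
            if gs_active:
                pool_crit = (_gebv_for(gebvs, cohort, AYT)[sel]
                             + gebvs["_means"][AYT])
            else:
                pool_crit = criterion[sel]
            pool_additions.append(dict(
                year=year, haps=cohort.haps[sel].copy(),
                tbv=cohort.tbv[sel].copy(), ids=cohort.ids[sel].copy(),
                criterion=pool_crit.copy(), cycle=cycle,
                orig=cohort.orig_index[sel].copy()))
            kids = meiosis.self_batch(cohort.haps, sel, layout, rng)
            next_stage = f"F{g + 1}"
            carried = (selection_accuracy(criterion[sel],
                                          cohort.tbv[sel, AYT])
                       if g == 7 else float("nan"))
            new_cohorts[cycle] = Cohort(
                cycle=cycle, stage=next_stage, haps=kids,
                ids=state.take_ids(kids.shape[0]), family=cohort.family[sel],
                tbv=model.tbv(kids), orig_index=cohort.orig_index[sel],
                carried_accuracy=carried)

    # refresh stored parent criteria from this year's genomic solve: stored
    # lines whose cohort is still in the reference window get their current
    # absolute-scale AYT GEBV (their later yield records sharpen it)
    if gs_active and gebvs:
        mean_ayt = gebvs["_means"][AYT]
        for entry in state.pool.entries:
            c = entry.get("cycle", -1)
            if c in gebvs and entry.get("orig") is not None:
                orig, scores = gebvs[c]
                pos = {int(o): r for r, o in enumerate(orig)}
                rows = np.array([pos.get(int(o), -1) for o in entry["orig"]])
                ok = rows >= 0
                if ok.any():
                    crit = entry["criterion"].copy()
                    crit[ok] = scores[rows[ok], AYT] + mean_ayt
                    entry["criterion"] = crit

    # --- new cycle: parent draw and crossing block ---------------------------
    selection = config.parent_selection
    if selection == "auto":
        selection = "truncation" if gs_active else "random"
    window = (config.truncation_window if selection == "truncation"
              else config.parent_pool_window)
    parent_haps, parent_tbv, _parent_ids = draw_parents(
        state.pool, config.n_parents, year, rng,
        window=window, selection=selection)
    pairs = make_crosses(config.n_parents, config.n_crosses,
                         config.max_crosses_per_parent, rng)
    f1_haps = meiosis.cross_batch(parent_haps, pairs, layout, rng)
    new_cohorts[year] = Cohort(
        cycle=year, stage="F1", haps=f1_haps,
        ids=state.take_ids(config.n_crosses),
        family=np.arange(config.n_crosses, dtype=np.int64),
        tbv=model.tbv(f1_haps),
        orig_index=np.full(config.n_crosses, -1, dtype=np.int64))

    for add in pool_additions:
        state.pool.add(**add)
    state.pool.prune(year, config.parent_pool_window)

    state.cohorts = new_cohorts
    _evict_old(state, year, config)
    return state


def _evict_old(state: ProgramState, year: int, config: SchemeConfig):
    horizon = year - 8
    for c in [c for c in state.cohort_info if c < horizon]:
        del state.cohort_info[c]
    for c in [c for c in state.zc_cache if c < horizon]:
        del state.zc_cache[c]
    for key in [k for k in state.grm_cache if min(k) < horizon]:
        del state.grm_cache[key]


# ---------------------------------------------------------------------------
# full program
# ---------------------------------------------------------------------------

@dataclass
class ProgramOutput:
    """Per-year, per-stage summaries of one replicate of one scenario."""

    stage_stats: pd.DataFrame
    config: SchemeConfig
    seed: int
    replicate: int = 0

    def to_csv(self, path):
        self.stage_stats.to_csv(path, index=False)


def initialize_state(config: SchemeConfig, seed: int) -> ProgramState:
    """Build layout, founders, base population and trait model."""
    config.validate()
    ss = np.random.SeedSequence(seed)
    r_layout, r_founder, r_base, r_traits, r_prog = \
        [np.random.default_rng(s) for s in ss.spawn(5)]

    layout = genome.build_genome_layout(
        config.n_loci, config.n_qtl, config.n_chromosomes,
        config.map_length_cM, r_layout)
    pool = genome.simulate_founder_pool(layout, config.n_founders,
                                        rng=r_founder)
    if config.marker_thin_step:
        keep = genome.thin_markers(layout, config.marker_thin_step)
        pool = pool.subset_loci(keep)
        layout = pool.layout
    base_haps = genome.sample_base_population(pool, config.n_base, r_base)
    model = traits.build_trait_model(
        layout, base_haps, config.corr_pyt_ayt, r_traits,
        corr_bvp=config.corr_bvp, h2_bvp=config.h2_bvp,
        h2_pyt=config.h2_pyt, h2_ayt=config.h2_ayt,
        n_plants={"PYT": config.pyt_plot_plants,
                  "AYT": config.ayt_plot_plants},
        residual_mode=config.residual_mode)
    base_tbv = model.tbv(base_haps)
    base_freq = base_haps.sum(axis=1).mean(axis=0) / 2.0
    marker_freq = base_freq[layout.marker_idx]

    state = ProgramState(
        year=0, layout=layout, model=model,
        pool=ParentPool(base_haps=base_haps, base_tbv=base_tbv),
        marker_freq=marker_freq)
    state._program_rng = r_prog  # kept on state for run_program
    return state


def run_program(config: SchemeConfig, seed: int,
                replicate: int = 0) -> ProgramOutput:
    """Run one replicate of one scenario for ``config.years`` years.

    Deterministic given ``seed``; replicates differ only by seed.  The
    output holds one row per (year, stage) with TBV means/variances for the
    three traits, the selection accuracy at decision stages, and the
    genomic-reference size.
    """
    state = initialize_state(config, seed)
    rng = state._program_rng
    for _ in range(config.years):
        advance_year(state, config, rng)
    stats = pd.DataFrame(state.stats_rows)
    stats.insert(0, "replicate", replicate)
    stats.insert(0, "corr_pyt_ayt", config.corr_pyt_ayt)
    stats.insert(0, "strategy", config.strategy)
    return ProgramOutput(stage_stats=stats, config=config, seed=seed,
                         replicate=replicate)
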