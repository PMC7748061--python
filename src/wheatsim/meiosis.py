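"""Gamete formation, crossing and selfing for inbred-line breeding.

Recombination follows Haldane's model: crossover counts per chromosome are
Poisson with mean ``map_length_cM / 100`` and crossover positions are uniform
on the chromosome, with no interference.  Gametes are mosaics of the two
parental haplotypes, starting from a fair-coin choice of strand.  There is no
mutation, so every offspring allele is a copy of a parental allele.

The module exposes both a per-individual API (:func:`simulate_gamete`,
:func:`cross`, :func:`self_line`) used in tests and small examples, and batch
routines (:func:`gametes_batch`, :func:`cross_batch`, :func:`self_batch`)
that the breeding-scheme engine uses to produce thousands of seeds per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

#: hard cap on crossovers per chromosome; P(Poisson(1.5) > 12) ~ 1e-9
MAX_CROSSOVERS = 12


# ---------------------------------------------------------------------------
# low-level mosaic kernel
# ---------------------------------------------------------------------------

def _fill_gametes_py(haps, parent_idx, chrom_starts, pos, n_xo, xo_pos,
                     start_hap, out):
    n = parent_idx.shape[0]
    n_chrom = chrom_starts.shape[0] - 1
    for g in range(n):
        p = parent_idx[g]
        for c in range(n_chrom):
            lo = chrom_starts[c]
            hi = chrom_starts[c + 1]
            h = start_hap[g, c]
            k = 0
            kmax = n_xo[g, c]
            for loc in range(lo, hi):
                while k < kmax and xo_pos[g, c, k] < pos[loc]:
                    h = 1 - h
                    k += 1
                out[g, loc] = haps[p, h, loc]


if _HAVE_NUMBA:
    _fill_gametes = njit(cache=True)(_fill_gametes_py)
else:  # pragma: no cover
    _fill_gametes = _fill_gametes_py


def _draw_crossovers(n: int, layout, rng):
    """Sample crossover counts, sorted positions and starting strands."""
    n_chrom = layout.n_chromosomes
    lam = layout.map_length / 100.0  # Morgans = expected crossovers
    n_xo = rng.poisson(lam, size=(n, n_chrom))
    np.clip(n_xo, 0, MAX_CROSSOVERS, out=n_xo)
    xo_pos = rng.uniform(0.0, 1.0, size=(n, n_chrom, MAX_CROSSOVERS))
    xo_pos *= layout.map_length[None, :, None]
    # invalidate entries beyond the drawn count, then sort so that the
    # first n_xo entries per (gamete, chromosome) are the ordered positions
    invalid = np.arange(MAX_CROSSOVERS)[None, None, :] >= n_xo[:, :, None]
    xo_pos[invalid] = np.inf
    xo_pos.sort(axis=2)
    start_hap = rng.integers(0, 2, size=(n, n_chrom), dtype=np.int8)
    return n_xo, xo_pos, start_hap


def gametes_batch(haps: np.ndarray, parent_idx: np.ndarray, layout,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete from each of ``parent_idx`` parents.

    Parameters
    ----------
    haps
        Parental haplotypes, shape ``(n_parents, 2, n_loci)``, int8 alleles.
    parent_idx
        For each gamete, the row of ``haps`` to sample from.
    layout
        A :class:`~wheatsim.genome.GenomeLayout`.
    rng
        Seeded generator; the draw is fully determined by it.

    Returns
    -------
    ndarray of shape ``(len(parent_idx), n_loci)``, int8.
    """
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    n = parent_idx.shape[0]
    n_xo, xo_pos, start_hap = _draw_crossovers(n, layout, rng)
    out = np.empty((n, layout.n_loci), dtype=np.int8)
    _fill_gametes(haps, parent_idx, layout.chrom_starts, layout.pos,
                  n_xo, xo_pos, start_hap, out)
    return out


def cross_batch(haps: np.ndarray, pairs: np.ndarray, layout,
                rng: np.random.Generator) -> np.ndarray:
    """Mate ``pairs[:, 0] x pairs[:, 1]``; returns offspring ``(n, 2, L)``."""
    pairs = np.asarray(pairs, dtype=np.int64)
    gam_a = gametes_batch(haps, pairs[:, 0], layout, rng)
    gam_b = gametes_batch(haps, pairs[:, 1], layout, rng)
    return np.stack([gam_a, gam_b], axis=1)


def self_batch(haps: np.ndarray, parent_idx: np.ndarray, layout,
               rng: np.random.Generator) -> np.ndarray:
    """Self-pollinate: two independent gametes from the same parent."""
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    gam_a = gametes_batch(haps, parent_idx, layout, rng)
    gam_b = gametes_batch(haps, parent_idx, layout, rng)
    return np.stack([gam_a, gam_b], axis=1)


# ---------------------------------------------------------------------------
# per-individual API
# ---------------------------------------------------------------------------

@dataclass
class Line:
    """One plant or inbred line: a pair of haplotypes plus bookkeeping tags."""

    id: int
    haplotypes: np.ndarray  # (2, n_loci) int8
    generation: str = "P"
    family_id: int = -1
    cycle_id: int = -1
    year_created: int = 0

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)

    def is_inbred(self) -> bool:
        return bool(np.array_equal(self.haplotypes[0], self.haplotypes[1]))


@dataclass
class GameteDraw:
    """A single gamete together with the crossover positions that made it."""

    haplotype: np.ndarray  # (n_loci,) int8
    crossover_positions: list = field(default_factory=list)  # per chromosome


def _as_hap_pair(parent) -> np.ndarray:
    hp = parent.haplotypes if isinstance(parent, Line) else np.asarray(parent)
    if hp.ndim != 2 or hp.shape[0] != 2:
        raise ValueError("parent haplotypes must have shape (2, n_loci)")
    return np.ascontiguousarray(hp, dtype=np.int8)


def simulate_gamete(parent, layout, rng: np.random.Generator) -> GameteDraw:
    """Form one gamete from ``parent`` under Haldane recombination."""
    hp = _as_hap_pair(parent)
    if hp.shape[1] != layout.n_loci:
        raise ValueError("parent does not conform to layout")
    n_xo, xo_pos, start_hap = _draw_crossovers(1, layout, rng)
    out = np.empty((1, layout.n_loci), dtype=np.int8)
    _fill_gametes(hp[None, :, :], np.zeros(1, dtype=np.int64),
                  layout.chrom_starts, layout.pos, n_xo, xo_pos, start_hap, out)
    positions = [xo_pos[0, c, :n_xo[0, c]].copy()
                 for c in range(layout.n_chromosomes)]
    return GameteDraw(haplotype=out[0], crossover_positions=positions)


def cross(parent_a, parent_b, layout, rng: np.random.Generator, *,
          id: int = 0, family_id: int = -1, cycle_id: int = -1,
          year: int = 0) -> Line:
    """Cross two parents; the F1 receives one gamete from each."""
    ha = _as_hap_pair(parent_a)
    hb = _as_hap_pair(parent_b)
    if ha.shape != hb.shape or ha.shape[1] != layout.n_loci:
        raise ValueError("parents incompatible with layout")
    gam_a = simulate_gamete(ha, layout, rng).haplotype
    gam_b = simulate_gamete(hb, layout, rng).haplotype
    return Line(id=id, haplotypes=np.stack([gam_a, gam_b]), generation="F1",
                family_id=family_id, cycle_id=cycle_id, year_created=year)


_GEN_ORDER = ["P", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8"]


def _next_generation(label: str) -> str:
    try:
        i = _GEN_ORDER.index(label)
    except ValueError:
        return label
    return _GEN_ORDER[min(i + 1, len(_GEN_ORDER) - 1)]


def self_line(parent: Line, n_offspring: int, layout,
              rng: np.random.Generator, *, first_id: int = 0) -> list[Line]:
    """Self ``parent``; each seed is the union of two independent gametes."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    hp = _as_hap_pair(parent)
    kids = self_batch(hp[None, :, :],
                      np.zeros(n_offspring, dtype=np.int64), layout, rng)
    gen = _next_generation(parent.generation)
    return [Line(id=first_id + k, haplotypes=kids[k], generation=gen,
                 family_id=parent.family_id, cycle_id=parent.cycle_id)
            for k in range(n_offspring)]


def expected_homozygosity(generation_index: int) -> float:
    """Expected homozygosity H at selfing generation t (F1: t=1).

    At loci segregating in the F1, selfing without selection halves
    heterozygosity every generation, so ``H = 1 - (1/2)**(t-1)``.
    """
    t = int(generation_index)
    if t < 1:
        raise ValueError("generation index must be >= 1 (F1 is 1)")
    return 1.0 - 0.5 ** (t - 1)


def haldane_recombination_fraction(d_cM: float) -> float:
    """Haldane map function: c = (1 - exp(-2d/100)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))
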