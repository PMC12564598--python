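"""Synthetic colony screens, genomes, and gene sets with known ground truth.

The generator emulates a fission-yeast deletion-library screen: a
3420-mutant library arrayed at 1536 density (32 x 48), each mutant pinned
in quadruplicate (2 x 2 replicate-spot blocks, the standard condensation of
a 384-format library), three biological replicates per condition, and two
genetic backgrounds (query double mutants vs a marker-only wild-type
control).  Colony sizes follow a multiplicative model::

    size(r, c) = base * fitness_g * 2^effect (query only)
               * row_factor_r * col_factor_c * gradient(r, c) * edge(r, c)
               * 2^eps,   eps ~ Normal(0, sigma)

with lognormal pixel noise (sigma in log2 units), random dropout (absent
colonies) and occasional tiny colonies, so every QC and normalization stage
has something to remove.  Planted per-gene interaction effects apply only
in the query background, giving an exact expected GIS per gene.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .plate_io import (
    EMPTY, GeneAnnotation, LibraryLayout, PlateGrid,
    REASON_ABSENT, REASON_NONE,
    write_colony_table, write_gff3, write_layout,
)

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI"]


def gene_ids(n: int) -> list[str]:
    """Systematic-style synthetic gene identifiers SYNG0001..SYNG<n>."""
    width = max(4, len(str(n)))
    return [f"SYNG{i:0{width}d}" for i in range(1, n + 1)]


@dataclass
class TruthConfig:
    """Generative parameters of a synthetic screen.

    Defaults are the study conditions the pipeline is designed for: base
    colony area 400 px, per-gene fitness spread 0.2 (log2 sd), 10% of genes
    carrying an interaction effect of magnitude 1 log2 unit (random sign),
    row/column factors with 0.1 log2 sd, a +/-30% smooth gradient, a 1.3x
    boost on the outermost two rows/columns, lognormal pixel noise of 0.15
    log2 units, 2% dropout and 1% tiny colonies.
    """

    base_size: float = 400.0
    gene_fitness_sigma: float = 0.2
    effect_fraction: float = 0.1
    effect_size: float = 1.0
    gene_effects: dict[str, float] | None = None
    row_sigma: float = 0.1
    col_sigma: float = 0.1
    gradient_amplitude: float = 0.3
    edge_boost: float = 1.3
    edge_width: int = 2
    noise_sigma: float = 0.15
    dropout_rate: float = 0.02
    small_rate: float = 0.01


@dataclass
class ScreenTruth:
    """Every stochastic choice made while generating a screen."""

    seed: int
    gene_effects: dict[str, float]
    gene_fitness: dict[str, float]
    row_factors: np.ndarray
    col_factors: np.ndarray
    gradient: np.ndarray
    edge_boost: float
    edge_width: int
    noise_sigma: float
    dropout_rate: float
    small_rate: float
    base_size: float

    def interactors(self) -> set[str]:
        return {g for g, e in self.gene_effects.items() if e != 0.0}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "gene_effects": self.gene_effects,
            "gene_fitness": self.gene_fitness,
            "row_factors": [float(x) for x in self.row_factors],
            "col_factors": [float(x) for x in self.col_factors],
            "gradient": [[float(x) for x in row] for row in self.gradient],
            "edge_boost": self.edge_boost,
            "edge_width": self.edge_width,
            "noise_sigma": self.noise_sigma,
            "dropout_rate": self.dropout_rate,
            "small_rate": self.small_rate,
            "base_size": self.base_size,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)


@dataclass
class SimulatedScreen:
    plates: list[PlateGrid]
    layout: LibraryLayout
    truth: ScreenTruth

    def write(self, outdir: str | Path) -> list[Path]:
        """Write plates (.dat), layout.tsv and truth.json into a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for grid in self.plates:
            name = (f"{grid.plate_id}_{grid.condition}_{grid.background}"
                    f"_rep{grid.replicate}.dat")
            write_colony_table(grid, outdir / name)
            paths.append(outdir / name)
        write_layout(self.layout, outdir / "layout.tsv")
        self.truth.to_json(outdir / "truth.json")
        return paths


def _make_layout(
    n_genes: int, plate_format: tuple[int, int], n_replicate_spots: int,
    ids: list[str],
) -> tuple[LibraryLayout, int]:
    """Tile genes onto plates; quadruplicate spots form 2 x 2 blocks."""
    nr, nc = plate_format
    if n_replicate_spots == 1:
        block_rows, block_cols = nr, nc
        offsets = [(0, 0)]
    elif n_replicate_spots == 4:
        if nr % 2 or nc % 2:
            raise ValueError("quadruplicate spots need an even plate format")
        block_rows, block_cols = nr // 2, nc // 2
        offsets = [(0, 0), (0, 1), (1, 0), (1, 1)]
    else:
        raise ValueError("n_replicate_spots must be 1 or 4")
    genes_per_plate = block_rows * block_cols
    n_plates = math.ceil(n_genes / genes_per_plate)
    entries: dict[tuple[str, int, int], str] = {}
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        for b in range(genes_per_plate):
            idx = p * genes_per_plate + b
            gene = ids[idx] if idx < n_genes else EMPTY
            br, bc = divmod(b, block_cols)
            scale = 2 if n_replicate_spots == 4 else 1
            for dr, dc in offsets:
                entries[(plate_id, scale * br + dr + 1, scale * bc + dc + 1)] = gene
    return LibraryLayout(entries=entries), n_plates


def simulate_screen(
    n_genes: int = 3420,
    plate_format: tuple[int, int] = (32, 48),
    n_reps: int = 3,
    conditions: tuple[str, ...] = ("untreated", "CAP"),
    truth_config: TruthConfig | None = None,
    seed: int = 0,
    n_replicate_spots: int = 4,
) -> SimulatedScreen:
    """Generate a full arrayed screen with planted ground truth.

    Returns plates for every (condition, background, replicate, plate)
    combination, the library layout, and the :class:`ScreenTruth` that
    fully specifies the generative process.
    """
    cfg = truth_config or TruthConfig()
    nr, nc = plate_format
    rng = np.random.default_rng(seed)
    ids = gene_ids(n_genes)

    layout, n_plates = _make_layout(n_genes, plate_format, n_replicate_spots, ids)
    if n_genes > n_plates * (nr * nc) // n_replicate_spots:
        raise ValueError("library does not fit the plate format")

    # --- planted truth (drawn once, shared across plates) ---
    fitness = 2.0 ** rng.normal(0.0, cfg.gene_fitness_sigma, n_genes)
    if cfg.gene_effects is not None:
        effects = {g: float(cfg.gene_effects.get(g, 0.0)) for g in ids}
    else:
        effects = {g: 0.0 for g in ids}
        n_eff = int(round(cfg.effect_fraction * n_genes))
        chosen = rng.choice(n_genes, size=n_eff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_eff)
        for i, s in zip(chosen, signs):
            effects[ids[i]] = s * cfg.effect_size

    row_factors = 2.0 ** rng.normal(0.0, cfg.row_sigma, nr)
    col_factors = 2.0 ** rng.normal(0.0, cfg.col_sigma, nc)

    theta = rng.uniform(0.0, 2.0 * np.pi)
    x = (np.arange(nr) / max(nr - 1, 1) - 0.5)[:, None]
    y = (np.arange(nc) / max(nc - 1, 1) - 0.5)[None, :]
    direction = math.cos(theta) * x + math.sin(theta) * y
    norm = (abs(math.cos(theta)) + abs(math.sin(theta))) / 2.0
    gradient = 1.0 + cfg.gradient_amplitude * direction / norm if norm > 0 \
        else np.ones((nr, nc))
    gradient = np.broadcast_to(gradient, (nr, nc)).copy()

    edge = np.ones((nr, nc))
    w = cfg.edge_width
    if w > 0 and cfg.edge_boost != 1.0:
        edge[:w, :] = edge[-w:, :] = cfg.edge_boost
        edge[:, :w] = np.maximum(edge[:, :w], cfg.edge_boost)
        edge[:, -w:] = np.maximum(edge[:, -w:], cfg.edge_boost)

    truth = ScreenTruth(
        seed=seed, gene_effects=effects,
        gene_fitness=dict(zip(ids, map(float, fitness))),
        row_factors=row_factors, col_factors=col_factors, gradient=gradient,
        edge_boost=cfg.edge_boost, edge_width=w, noise_sigma=cfg.noise_sigma,
        dropout_rate=cfg.dropout_rate, small_rate=cfg.small_rate,
        base_size=cfg.base_size,
    )

    # --- per-plate base matrices from the layout ---
    fitness_by_id = truth.gene_fitness
    plate_ids = [f"P{p + 1:02d}" for p in range(n_plates)]
    base_fit = {}
    base_eff = {}
    for pid in plate_ids:
        fit = np.zeros((nr, nc))
        eff = np.zeros((nr, nc))
        for r in range(nr):
            for c in range(nc):
                gene = layout.gene_at(pid, r + 1, c + 1)
                if gene is None or gene == EMPTY:
                    fit[r, c] = 0.0
                else:
                    fit[r, c] = fitness_by_id[gene]
                    eff[r, c] = effects[gene]
        base_fit[pid] = fit
        base_eff[pid] = eff

    bias = row_factors[:, None] * col_factors[None, :] * gradient * edge
    ln2 = math.log(2.0)

    plates: list[PlateGrid] = []
    for condition in conditions:
        for background in ("query", "control"):
            for rep in range(1, n_reps + 1):
                for pid in plate_ids:
                    mean = cfg.base_size * base_fit[pid] * bias
                    if background == "query":
                        mean = mean * 2.0 ** base_eff[pid]
                    eps = rng.normal(0.0, cfg.noise_sigma * ln2, (nr, nc))
                    size = mean * np.exp(eps)
                    dropout = rng.random((nr, nc)) < cfg.dropout_rate
                    small = rng.random((nr, nc)) < cfg.small_rate
                    small_sizes = rng.integers(1, 50, (nr, nc)).astype(float)

                    empty = base_fit[pid] == 0.0
                    size[empty | dropout] = 0.0
                    tiny = small & ~empty & ~dropout
                    size[tiny] = small_sizes[tiny]

                    absent = size == 0.0
                    reason = np.full((nr, nc), REASON_NONE, dtype="<U8")
                    reason[absent] = REASON_ABSENT
                    plates.append(PlateGrid(
                        plate_id=pid, condition=condition,
                        background=background, replicate=rep,
                        n_rows=nr, n_cols=nc, size=size, mask=absent,
                        mask_reason=reason,
                    ))
    return SimulatedScreen(plates=plates, layout=layout, truth=truth)


def simulate_genome(
    n_genes: int = 3420,
    n_chromosomes: int = 3,
    chrom_length: int = 4_000_000,
    gene_length: int = 1500,
    spacing: int = 2000,
    seed: int = 0,
) -> GeneAnnotation:
    """Deterministically tile genes along chromosomes.

    Gene j (1-based within its chromosome) occupies
    ``[1 + (j-1)*(gene_length+spacing), 1 + (j-1)*(gene_length+spacing) +
    gene_length - 1]``, so the set of genes within any distance of any
    locus is analytically computable.  Genes are split as evenly as
    possible across chromosomes, in ID order.  ``seed`` is accepted for
    interface symmetry; the tiling is deterministic.
    """
    del seed
    ids = gene_ids(n_genes)
    per = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per[i] += 1
    pitch = gene_length + spacing
    records: dict[str, tuple[str, int, int]] = {}
    idx = 0
    for ci, count in enumerate(per):
        chrom = "chr" + _ROMAN[ci] if ci < len(_ROMAN) else f"chr{ci + 1}"
        for j in range(count):
            start = 1 + j * pitch
            end = start + gene_length - 1
            if end > chrom_length:
                raise ValueError(
                    f"{chrom}: gene {ids[idx]} overflows chromosome length"
                )
            records[ids[idx]] = (chrom, start, end)
            idx += 1
    return GeneAnnotation(records=records)


def write_genome(annotation: GeneAnnotation, path: str | Path) -> None:
    """GFF3 serialization of a simulated genome (round-trips via read_gff3)."""
    write_gff3(annotation, path)


def simulate_gene_sets(
    background_n: int,
    sizes: list[int],
    planted_overlap: int | None = None,
    seed: int = 0,
) -> tuple[list["GeneSet"], list[str]]:
    """Gene sets over a synthetic background, for overlap-test fixtures.

    With ``planted_overlap`` given, all sets share exactly that many
    members and their remaining members are drawn disjointly, so every
    pairwise and total intersection equals the planted value.  With
    ``planted_overlap=None`` each set is an independent uniform random
    subset (the null of the overlap tests).
    """
    from .overlap_stats import GeneSet

    background = gene_ids(background_n)
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    if planted_overlap is None:
        for i, s in enumerate(sizes):
            if s > background_n:
                raise ValueError("set size exceeds background")
            members = rng.choice(background_n, size=s, replace=False)
            sets.append(GeneSet(f"set{i + 1}", {background[j] for j in members}))
        return sets, background

    if planted_overlap > min(sizes):
        raise ValueError("planted overlap exceeds the smallest set")
    extra = sum(s - planted_overlap for s in sizes)
    if planted_overlap + extra > background_n:
        raise ValueError("sets do not fit disjointly in the background")
    perm = rng.permutation(background_n)
    core = [background[j] for j in perm[:planted_overlap]]
    cursor = planted_overlap
    for i, s in enumerate(sizes):
        own = [background[j] for j in perm[cursor:cursor + s - planted_overlap]]
        cursor += s - planted_overlap
        sets.append(GeneSet(f"set{i + 1}", set(core) | set(own)))
    return sets, background
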