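"""Synthetic expression datasets with planted, recoverable structure.

Every downstream stage of the pipeline (hourglass curve, gene contributions,
enrichment, region embeddings, cross-species correlation) is exercised on
data generated here, so each statistical signal the pipeline is supposed to
detect is planted explicitly and recorded in :class:`GroundTruth`:

* a **temporal envelope** controlling how strong region-specific expression
  is at each age — U-shaped by default, so mean inter-region dissimilarity
  dips mid-series (the hourglass);
* two **gene programs**: "construction" genes whose regional signal follows
  the declining (embryonic) limb of the envelope and "plasticity" genes
  following the rising (postnatal) limb, plus unstructured null genes;
* **lineage blocks**: regions grouped by embryonic origin share a per-gene
  loading, making within-block pairs more similar than across-block pairs;
* **planted GO categories** drawn from the program genes (plus size-matched
  random distractor categories as a calibrated null);
* **paralog pairs** whose region loadings have an exact target correlation;
* an optional **breakaway region** given an extra, ramping loading on a set
  of driver genes, emulating postnatal cerebellar divergence.

The additive model for one cell is::

    value(g, r, t) = baseline(g)
                     + envelope(program(g), t) * pattern(g, r)
                     + lineage_strength * block_loading(g, block(r))
                     + breakaway(g, r, t)
                     + Normal(0, noise_sd),   clipped at 0

with ``pattern(g, r) ~ N(0, 1)`` i.i.d.  Baselines are Uniform(3, 6) so that
clipping at zero is rare and correlations stay essentially unbiased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_core import ExpressionDataset, OrthologMap, ValidationError

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "EMBRYONIC_TIMEPOINTS",
    "POSTNATAL_TIMEPOINTS",
    "SyntheticConfig",
    "GroundTruth",
    "u_envelope",
    "generate",
    "generate_counterpart",
    "write_synthetic_inputs",
]

# developing-brain atlas age series: four embryonic, three postnatal ages.
DEFAULT_TIMEPOINTS = ("E11.5", "E13.5", "E15.5", "E18.5", "P4", "P14", "P28")
EMBRYONIC_TIMEPOINTS = ("E11.5", "E13.5", "E15.5", "E18.5")
POSTNATAL_TIMEPOINTS = ("P4", "P14", "P28")

ORIGIN_BLOCKS = (
    "forebrain-telencephalon",
    "forebrain-diencephalon",
    "midbrain",
    "hindbrain",
)


def u_envelope(n_timepoints: int, peak: float = 1.0, floor: float = 0.05) -> np.ndarray:
    """Symmetric U-shaped envelope over timepoint ranks.

    Quadratic in the rank, equal to ``peak`` at both ends and ``floor`` at
    the midpoint — the default temporal profile of region-signal magnitude.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    mid = (n_timepoints - 1) / 2.0
    x = (np.arange(n_timepoints) - mid) / mid
    return floor + (peak - floor) * x**2


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic generator; the seed fully determines output."""

    n_genes: int = 200
    n_regions: int = 12
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS
    envelope: np.ndarray | None = None  # default: u_envelope(len(timepoints))
    frac_construction: float = 0.3
    frac_plasticity: float = 0.3
    lineage_strength: float = 0.3
    n_origin_blocks: int = 4
    baseline_range: tuple[float, float] = (3.0, 6.0)
    noise_sd: float = 0.1
    # planted GO structure
    planted_category_size: int = 20
    n_planted_per_program: int = 1
    n_distractor_categories: int = 20
    planted_amplification: float = 2.0
    # paralog pairs (taken from construction genes)
    n_paralog_pairs: int = 5
    paralog_target_correlation: float = -0.6
    # optional breakaway region (postnatally diverging by default)
    breakaway_region: str | None = None
    n_breakaway_drivers: int = 20
    breakaway_strength: float = 1.0
    breakaway_index_targets: tuple[float, ...] = (1.25, 1.45, 1.65)
    breakaway_phase: str = "postnatal"  # or "embryonic"
    seed: int = 0

    def resolved_envelope(self) -> np.ndarray:
        env = (u_envelope(len(self.timepoints)) if self.envelope is None
               else np.asarray(self.envelope, dtype=float))
        if env.shape != (len(self.timepoints),):
            raise ValidationError("envelope length must match timepoints")
        if (env < 0).any():
            raise ValidationError("envelope must be non-negative")
        return env

    def validate(self) -> None:
        if self.frac_construction + self.frac_plasticity > 1.0 + 1e-12:
            raise ValidationError("program fractions must sum to <= 1")
        if not 0 <= self.frac_construction and 0 <= self.frac_plasticity:
            raise ValidationError("program fractions must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not -1.0 <= self.paralog_target_correlation <= 1.0:
            raise ValidationError("paralog target correlation must be in [-1, 1]")
        self.resolved_envelope()


@dataclass
class GroundTruth:
    """Everything that was planted, for downstream recovery checks."""

    program: dict[str, str]              # gene -> construction|plasticity|null
    region_block: dict[str, str]         # region -> origin tag
    planted_categories: dict[str, list[str]]    # category id -> gene list
    distractor_categories: dict[str, list[str]]
    paralog_pairs: list[tuple[str, str]]
    envelope: np.ndarray = field(default_factory=lambda: np.array([]))
    breakaway_region: str | None = None
    breakaway_drivers: list[str] = field(default_factory=list)

    def annotation_table(self) -> list[tuple[str, str]]:
        """(gene, category) rows for planted and distractor categories."""
        rows = []
        for cat, genes in {**self.planted_categories,
                           **self.distractor_categories}.items():
            rows.extend((g, cat) for g in genes)
        return rows


def _program_envelopes(envelope: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a U envelope into declining (construction) and rising
    (plasticity) limbs, each flat at the envelope minimum past its own limb."""
    t_min = int(np.argmin(envelope))
    floor = float(envelope[t_min])
    e_con = envelope.copy()
    e_con[t_min + 1:] = floor
    e_pla = envelope.copy()
    e_pla[:t_min] = floor
    return e_con, e_pla


def _exact_correlated(a: np.ndarray, z: np.ndarray, rho: float) -> np.ndarray:
    """Vector whose *sample* correlation with ``a`` is exactly ``rho``.

    Gram–Schmidt: standardize ``a``, orthogonalize ``z`` against it, mix.
    Returned vector is standardized (mean 0, sd 1) like the inputs' scale.
    """
    ac = (a - a.mean())
    ac /= ac.std()
    zc = z - z.mean()
    zc -= (zc @ ac) / (ac @ ac) * ac
    if np.allclose(zc, 0):
        raise ValueError("degenerate orthogonal complement")
    zc /= zc.std()
    b = rho * ac + np.sqrt(1.0 - rho**2) * zc
    return b / b.std()


def _p_same_block(block_of: dict[str, int]) -> float:
    """Probability that a random region pair shares a lineage block."""
    from collections import Counter

    counts = Counter(block_of.values())
    n = len(block_of)
    same = sum(c * (c - 1) for c in counts.values())
    return same / (n * (n - 1)) if n > 1 else 0.0


def _solve_breakaway_ramp(
    config: SyntheticConfig,
    e_con: np.ndarray,
    e_pla: np.ndarray,
    window: list[int],
    p_same_block: float,
) -> np.ndarray:
    """Per-timepoint driver loading scale that plants a target index profile.

    With i.i.d. standard-normal loadings the expected across-gene covariance
    between two region profiles and each region's variance follow in closed
    form from the config, so the extra variance the breakaway region needs
    in order to reach a target specialization index (its mean dissimilarity
    to other regions divided by the overall mean) can be solved directly.
    An open-loop ramp cannot do this: dissimilarity saturates near 1 while
    the brain-wide mean keeps rising, so matching an increasing index
    requires variance that grows super-geometrically.
    """
    targets = np.asarray(config.breakaway_index_targets, dtype=float)
    if len(targets) < len(window):
        raise ValidationError("breakaway_index_targets shorter than the "
                              "breakaway phase window")
    targets = targets[:len(window)]
    if config.breakaway_phase == "embryonic":
        targets = targets[::-1]

    G, R = config.n_genes, config.n_regions
    lo, hi = config.baseline_range
    var_base = (hi - lo) ** 2 / 12.0
    lin2 = config.lineage_strength**2
    n_con = int(round(config.frac_construction * G))
    n_pla = int(round(config.frac_plasticity * G))
    frac_drv = config.n_breakaway_drivers / G
    # planted categories carry an amplified envelope; their genes contribute
    # amp^2 times the program variance
    amp2 = config.planted_amplification**2
    n_amp_c = (config.n_planted_per_program * config.planted_category_size
               if n_con - 2 * min(config.n_paralog_pairs, n_con // 2)
               >= config.planted_category_size * config.n_planted_per_program
               else 0)
    n_amp_p = (config.n_planted_per_program * config.planted_category_size
               if n_pla >= config.planted_category_size
               * config.n_planted_per_program else 0)

    n_pairs = R * (R - 1) / 2
    w_rb = (R - 1) / n_pairs  # fraction of pairs involving the region

    ramp = np.zeros(len(e_con))
    for target, t in zip(targets, window):
        v_t = (((n_con - n_amp_c) + amp2 * n_amp_c) / G * e_con[t] ** 2
               + ((n_pla - n_amp_p) + amp2 * n_amp_p) / G * e_pla[t] ** 2)
        # drivers are flat marker genes: they contribute neither baseline
        # spread nor lineage loading, shrinking shared covariance by 1-frac
        cov = (1.0 - frac_drv) * (var_base + lin2 * p_same_block)
        var_r = ((1.0 - frac_drv) * (var_base + lin2)
                 + v_t + config.noise_sd**2)
        d_nn = max(1.0 - cov / var_r, 1e-9)
        # jointly solve d_rb = target * Dbar with Dbar mixing nn and rb pairs
        a = (1.0 - w_rb) * d_nn
        denom = 1.0 - target * w_rb
        if denom <= 0:
            raise ValidationError("breakaway index target infeasible for "
                                  f"{R} regions")
        d_rb = min(target * a / denom, 0.98)
        var_rb_needed = (cov / (1.0 - d_rb)) ** 2 / var_r
        extra = max(var_rb_needed - var_r, 0.0)
        # drivers all deviate upward by the same amount; after the Pearson
        # centering this contributes frac*(1-frac)*ramp^2 of variance and no
        # spurious covariance, and positive deviations never clip at zero
        ramp[t] = np.sqrt(extra / (frac_drv * (1.0 - frac_drv))) \
            / max(config.breakaway_strength, 1e-12)
    return ramp


def generate(config: SyntheticConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate one synthetic dataset plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, R = config.n_genes, config.n_regions
    tps = list(config.timepoints)
    T = len(tps)
    envelope = config.resolved_envelope()
    e_con, e_pla = _program_envelopes(envelope)

    genes = [f"g{i:04d}" for i in range(G)]
    regions = [f"r{j:02d}" for j in range(R)]

    # program assignment: first block construction, then plasticity, rest null
    n_con = int(round(config.frac_construction * G))
    n_pla = int(round(config.frac_plasticity * G))
    program = {}
    for i, g in enumerate(genes):
        program[g] = ("construction" if i < n_con
                      else "plasticity" if i < n_con + n_pla
                      else "null")
    env_by_gene = np.zeros((G, T))
    env_by_gene[:n_con] = e_con
    env_by_gene[n_con:n_con + n_pla] = e_pla

    # planted GO categories: per program, a block of genes with a shared,
    # amplified envelope — a coherent contribution profile is what makes a
    # category recoverable by clustering (a random sample of program genes
    # would scatter across magnitude-driven clusters); paralog genes are
    # kept out so the two planted signals stay independent.  Distractor
    # categories are size-matched random gene sets (the calibrated null).
    n_pairs = min(config.n_paralog_pairs, n_con // 2)
    planted: dict[str, list[str]] = {}
    pools = {"construction": list(range(2 * n_pairs, n_con)),
             "plasticity": list(range(n_con, n_con + n_pla))}
    cat_i = 0
    for prog_name, pool in pools.items():
        for _ in range(config.n_planted_per_program):
            if len(pool) < config.planted_category_size:
                continue
            cat_i += 1
            chosen = sorted(rng.choice(pool, size=config.planted_category_size,
                                       replace=False))
            pool = [i for i in pool if i not in set(chosen)]
            env_by_gene[chosen] *= config.planted_amplification
            planted[f"GO:P{cat_i:06d}"] = [genes[i] for i in chosen]

    # region lineage blocks (round-robin over the origin tags)
    n_blocks = min(config.n_origin_blocks, len(ORIGIN_BLOCKS), R)
    block_of = {r: j % n_blocks for j, r in enumerate(regions)}
    region_block = {r: ORIGIN_BLOCKS[block_of[r]] for r in regions}

    baseline = rng.uniform(*config.baseline_range, size=G)
    pattern = rng.standard_normal((G, R))
    block_loading = rng.standard_normal((G, n_blocks))

    # breakaway drivers are chosen up front: they are modelled as marker
    # genes — flat, mean-level expression in every region except the
    # breakaway one (no baseline spread, no lineage loading), so removing
    # one strips planted variance without touching shared covariance
    drv_idx: list[int] = []
    if config.breakaway_region is not None:
        if config.breakaway_region not in regions:
            raise ValidationError(
                f"breakaway region {config.breakaway_region!r} not generated")
        null_idx = [i for i, g in enumerate(genes) if program[g] == "null"]
        pool = null_idx if len(null_idx) >= config.n_breakaway_drivers \
            else list(range(G))
        drv_idx = sorted(rng.choice(pool, size=config.n_breakaway_drivers,
                                    replace=False))
        baseline[drv_idx] = np.mean(config.baseline_range)
        block_loading[drv_idx, :] = 0.0

    # paralog pairs: consecutive construction genes, loadings with exact
    # sample correlation equal to the target
    paralog_pairs: list[tuple[str, str]] = []
    n_pairs = min(config.n_paralog_pairs, n_con // 2)
    for p in range(n_pairs):
        ia, ib = 2 * p, 2 * p + 1
        pattern[ib] = _exact_correlated(pattern[ia], rng.standard_normal(R),
                                        config.paralog_target_correlation)
        paralog_pairs.append((genes[ia], genes[ib]))

    values = (baseline[:, None, None]
              + env_by_gene[:, None, :] * pattern[:, :, None]
              + config.lineage_strength
              * block_loading[:, [block_of[r] for r in regions], None])

    # breakaway region: driver genes (from the null pool when possible) gain
    # an extra loading on one region, ramping across the chosen phase
    breakaway_drivers: list[str] = []
    if config.breakaway_region is not None:
        jb = regions.index(config.breakaway_region)
        breakaway_drivers = [genes[i] for i in drv_idx]
        n_post = len(POSTNATAL_TIMEPOINTS) if tuple(tps) == DEFAULT_TIMEPOINTS else T // 2
        if config.breakaway_phase == "postnatal":
            window = list(range(T - n_post, T))
        elif config.breakaway_phase == "embryonic":
            window = list(range(n_post))
        else:
            raise ValidationError("breakaway_phase must be postnatal or embryonic")
        ramp = _solve_breakaway_ramp(config, e_con, e_pla, window,
                                     p_same_block=_p_same_block(block_of))
        # equal positive deviations: every driver carries the same share of
        # the planted variance (recoverable by contribution rank) and the
        # upward shift cannot be clipped at zero
        for i in drv_idx:
            values[i, jb, :] += config.breakaway_strength * ramp

    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)

    dataset = ExpressionDataset(genes, regions, tps, values, species="synthetic")

    distractors: dict[str, list[str]] = {}
    for d in range(config.n_distractor_categories):
        size = min(config.planted_category_size, G)
        chosen = rng.choice(genes, size=size, replace=False)
        distractors[f"GO:D{d + 1:06d}"] = sorted(chosen.tolist())

    truth = GroundTruth(program=program, region_block=region_block,
                        planted_categories=planted,
                        distractor_categories=distractors,
                        paralog_pairs=paralog_pairs, envelope=envelope,
                        breakaway_region=config.breakaway_region,
                        breakaway_drivers=breakaway_drivers)
    return dataset, truth


def generate_counterpart(
    dataset: ExpressionDataset,
    warp: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    timepoint_labels: Sequence[str] | None = None,
    species: str = "counterpart",
) -> tuple[ExpressionDataset, OrthologMap]:
    """Second-species dataset obtained by warping the developmental timeline.

    ``warp[j]`` is the (possibly fractional) source-timepoint rank that
    counterpart timepoint ``j`` samples, linearly interpolated; it must be
    strictly increasing and stay within the source range.  Gaussian noise of
    sd ``noise_sd`` is added after interpolation (clipped at 0).  An identity
    ortholog map over the source genes is returned.
    """
    warp = np.asarray(warp, dtype=float)
    if warp.ndim != 1 or len(warp) < 1:
        raise ValidationError("warp must be a non-empty 1-D sequence")
    if not np.all(np.diff(warp) > 0):
        raise ValidationError("warp must be strictly increasing (monotone)")
    if warp.min() < 0 or warp.max() > dataset.n_timepoints - 1:
        raise ValidationError("warp leaves the source timepoint range")

    if timepoint_labels is None:
        timepoint_labels = [f"H{j + 1}" for j in range(len(warp))]
    if len(timepoint_labels) != len(warp):
        raise ValidationError("timepoint_labels length must match warp")

    src = dataset.values  # G x R x T
    lo = np.floor(warp).astype(int)
    hi = np.minimum(lo + 1, dataset.n_timepoints - 1)
    frac = warp - lo
    vals = (1.0 - frac)[None, None, :] * src[:, :, lo] + frac[None, None, :] * src[:, :, hi]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = np.clip(vals + rng.normal(0.0, noise_sd, size=vals.shape), 0.0, None)
    counterpart = ExpressionDataset(list(dataset.genes), list(dataset.regions),
                                    list(timepoint_labels), vals, species=species)
    orthologs = OrthologMap([(g, g) for g in dataset.genes])
    return counterpart, orthologs


def write_synthetic_inputs(config: SyntheticConfig, out_dir: str | Path) -> dict[str, str]:
    """Generate and write expression TSV, ontology TSV, GO annotation TSV and
    ground-truth JSON; returns the path map (used by the CLI)."""
    from .io_core import write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate(config)
    paths = {
        "expression": str(out / "expression.tsv"),
        "ontology": str(out / "ontology.tsv"),
        "annotations": str(out / "go_annotations.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_expression(dataset, paths["expression"])
    with open(paths["ontology"], "w", encoding="utf-8") as fh:
        fh.write("child\tparent\torigin\n")
        fh.write("brain\t\t\n")
        for r in dataset.regions:
            fh.write(f"{r}\tbrain\t{truth.region_block[r]}\n")
    with open(paths["annotations"], "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for g, cat in truth.annotation_table():
            fh.write(f"{g}\t{cat}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump({
            "program": truth.program,
            "region_block": truth.region_block,
            "planted_categories": truth.planted_categories,
            "distractor_categories": truth.distractor_categories,
            "paralog_pairs": truth.paralog_pairs,
            "envelope": truth.envelope.tolist(),
            "breakaway_region": truth.breakaway_region,
            "breakaway_drivers": truth.breakaway_drivers,
        }, fh, indent=2)
    return paths
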