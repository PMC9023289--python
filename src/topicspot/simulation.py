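"""Ground-truth spot simulators and the labeled block fixture.

Synthetic spatial spots are built by aggregating raw counts of cells drawn
from a labeled single-cell matrix, so every spot carries an exact ground
truth.  Three generators are provided:

* fully random spots — 2 to 10 cells per spot, sampled uniformly; a spot
  whose aggregated total exceeds 25,000 UMIs is down-sampled to 20,000;
* a sequencing-depth series — 1,000 spots of 10 cells, down-sampled to a
  ladder of depths (20,000 ... 1,000); nested by default so each shallower
  level is a subsample of the previous one;
* a structured tumor-microenvironment dataset with four compartments (tumor
  core, invasive margin, tumor stroma, tertiary lymphoid structure).  Each
  compartment fixes the mean fractions of a co-localized cell-type pair
  (target Pearson correlation 0.7 across its spots), draws the remaining
  mass over the allowed "free" types from a symmetric Dirichlet, and
  excludes every other type entirely.

The block fixture is a miniature labeled single-cell reference: each cell
type owns a private block of high-rate marker genes on top of a shared
background, so marker selection and topic recovery can be validated against
a known answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellTypeLabels, ExpressionMatrix

log = logging.getLogger("topicspot")

__all__ = [
    "SimulatedDataset",
    "CompartmentRule",
    "table1_rules",
    "downsample_counts",
    "simulate_random_spots",
    "simulate_depth_series",
    "simulate_tme",
    "make_block_fixture",
]

UMI_CAP = 25_000
UMI_TARGET = 20_000


@dataclass
class SimulatedDataset:
    """A simulated spot matrix with its exact ground truth.

    ``truth`` is an N x J proportion matrix over ``cell_types`` (columns sum
    to 1); ``provenance`` lists the source cell ids of each spot;
    ``spot_region`` optionally labels each spot's compartment.
    """

    st_matrix: ExpressionMatrix
    truth: np.ndarray
    cell_types: list[str]
    provenance: list[list[str]]
    spot_region: list[str] | None = None

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth, index=self.cell_types,
                            columns=self.st_matrix.column_ids)


@dataclass
class CompartmentRule:
    """Composition rule of one simulated tissue compartment.

    ``fixed`` maps cell types to fixed mean fractions; ``pairs`` lists the
    co-localized type pairs whose realized fractions should correlate at the
    target rho; ``free`` types share the residual mass with random fractions.
    Types named nowhere are excluded from the compartment.
    """

    region: str
    n_spots: int
    fixed: dict[str, float]
    free: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.fixed.values()) >= 1.0:
            raise ValueError(
                f"region {self.region!r}: fixed fractions sum to "
                f"{sum(self.fixed.values()):.2f} >= 1"
            )
        if not self.fixed and not self.free:
            raise ValueError(f"region {self.region!r} allows no cell types")
        for a, b in self.pairs:
            if a not in self.fixed or b not in self.fixed:
                raise ValueError(
                    f"correlated pair ({a}, {b}) must have fixed fractions"
                )


def table1_rules() -> list[CompartmentRule]:
    """Default tumor-microenvironment compartment rules.

    Four compartments with co-localized pairs at fixed mean fractions:
    tumor core (malignant 50% / CD8T 30%), invasive margin (malignant 30% /
    fibroblasts 30%), tumor stroma (fibroblasts 50% with CD4T 30% in half of
    the spots and B 30% in the other half), and tertiary lymphoid structure
    (CD4T 30% / B 40%).  The remaining types allowed in each compartment get
    random fractions of the residual mass.
    """
    return [
        CompartmentRule(
            region="TC", n_spots=250,
            fixed={"Malignant": 0.5, "CD8T": 0.3},
            pairs=[("Malignant", "CD8T")],
            free=["CD4T", "Mono/Macro", "Mast"],
        ),
        CompartmentRule(
            region="IM", n_spots=250,
            fixed={"Malignant": 0.3, "Fibroblasts": 0.3},
            pairs=[("Malignant", "Fibroblasts")],
            free=["CD4T", "CD8T", "Tprolif", "B", "Plasma", "Mono/Macro",
                  "Mast", "Endothelial", "Myofibroblasts"],
        ),
        CompartmentRule(
            region="TS", n_spots=125,
            fixed={"Fibroblasts": 0.5, "CD4T": 0.3},
            pairs=[("Fibroblasts", "CD4T")],
            free=["CD8T", "Tprolif", "Plasma", "Endothelial", "Myofibroblasts"],
        ),
        CompartmentRule(
            region="TS", n_spots=125,
            fixed={"Fibroblasts": 0.5, "B": 0.3},
            pairs=[("Fibroblasts", "B")],
            free=["CD8T", "Tprolif", "Plasma", "Endothelial", "Myofibroblasts"],
        ),
        CompartmentRule(
            region="TLS", n_spots=250,
            fixed={"CD4T": 0.3, "B": 0.4},
            pairs=[("CD4T", "B")],
            free=["CD8T", "Plasma", "Endothelial"],
        ),
    ]


def downsample_counts(
    v: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Down-sample a UMI count vector to exactly ``target`` total counts.

    Sampling is without replacement from the multiset of UMIs (multivariate
    hypergeometric), so the output is elementwise <= the input and sums to
    ``min(target, sum(v))``.
    """
    if target < 0:
        raise ValueError("target must be non-negative")
    v = np.asarray(v)
    if not np.issubdtype(v.dtype, np.integer):
        if not np.all(np.equal(np.mod(v, 1), 0)):
            raise ValueError("count vector must be integer")
        v = v.astype(np.int64)
    total = int(v.sum())
    if target >= total:
        return v.copy()
    return rng.multivariate_hypergeometric(v.astype(np.int64), target,
                                           method="marginals")


def _aggregate_spot(
    sc_values: np.ndarray,
    col_idx: np.ndarray,
    rng: np.random.Generator,
    umi_cap: int | None,
    umi_target: int | None,
) -> np.ndarray:
    col = sc_values[:, col_idx].sum(axis=1).astype(np.int64)
    if umi_cap is not None and col.sum() > umi_cap:
        col = downsample_counts(col, int(umi_target), rng)
    return col


def _truth_from_cells(
    cell_types_of: list[str], types: list[str]
) -> np.ndarray:
    t_idx = {t: i for i, t in enumerate(types)}
    v = np.zeros(len(types))
    for t in cell_types_of:
        v[t_idx[t]] += 1.0
    return v / v.sum()


def simulate_random_spots(
    sc: ExpressionMatrix,
    labels: CellTypeLabels,
    n_spots: int = 1000,
    cells_min: int = 2,
    cells_max: int = 10,
    umi_cap: int | None = UMI_CAP,
    umi_target: int = UMI_TARGET,
    seed: int = 0,
) -> SimulatedDataset:
    """Fully random spot mixtures of ``cells_min``..``cells_max`` cells.

    Cells are sampled uniformly without replacement within each spot and
    their raw counts summed; totals above ``umi_cap`` are down-sampled to
    ``umi_target``.  The ground truth is the cell-type frequency among the
    selected cells.
    """
    if not sc.is_integer:
        raise ValueError("simulation needs raw integer counts")
    if cells_max > sc.n_columns:
        raise ValueError("cells_max exceeds the number of available cells")
    if cells_min < 1 or cells_min > cells_max:
        raise ValueError("need 1 <= cells_min <= cells_max")
    labels.validate_against(sc)
    rng = np.random.default_rng(seed)
    types = labels.cell_types
    values = np.zeros((sc.n_genes, n_spots), dtype=np.int64)
    truth = np.zeros((len(types), n_spots))
    provenance: list[list[str]] = []
    for j in range(n_spots):
        k = int(rng.integers(cells_min, cells_max + 1))
        idx = rng.choice(sc.n_columns, size=k, replace=False)
        values[:, j] = _aggregate_spot(sc.values, idx, rng, umi_cap, umi_target)
        ids = [sc.column_ids[i] for i in idx]
        provenance.append(ids)
        truth[:, j] = _truth_from_cells([labels.assignments[c] for c in ids], types)
    st = ExpressionMatrix(values, list(sc.gene_ids),
                          [f"spot_{j}" for j in range(n_spots)], is_integer=True)
    return SimulatedDataset(st, truth, types, provenance)


def simulate_depth_series(
    sc: ExpressionMatrix,
    labels: CellTypeLabels,
    n_spots: int = 1000,
    cells_per_spot: int = 10,
    depths: list[int] = (20_000, 15_000, 10_000, 5_000, 2_500, 1_000),
    nested: bool = True,
    seed: int = 0,
) -> dict[int, SimulatedDataset]:
    """One base set of spots down-sampled to a ladder of sequencing depths.

    The ground truth and provenance are shared across levels.  With
    ``nested=True`` (default) each shallower level is a subsample of the next
    deeper one, so levels are directly comparable; otherwise each level is
    drawn independently from the base spots.
    """
    base = simulate_random_spots(
        sc, labels, n_spots=n_spots, cells_min=cells_per_spot,
        cells_max=cells_per_spot, umi_cap=None, seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    out: dict[int, SimulatedDataset] = {}
    prev = base.st_matrix.values
    for depth in sorted(set(int(d) for d in depths), reverse=True):
        src = prev if nested else base.st_matrix.values
        vals = np.zeros_like(src)
        shallow = []
        for j in range(src.shape[1]):
            total = int(src[:, j].sum())
            if depth >= total:
                shallow.append(base.st_matrix.column_ids[j])
                vals[:, j] = src[:, j]
            else:
                vals[:, j] = downsample_counts(src[:, j], depth, rng)
        if shallow:
            log.warning("%d spots already at or below depth %d kept at their "
                        "own total, e.g. %s", len(shallow), depth, shallow[:3])
        st = ExpressionMatrix(vals, list(base.st_matrix.gene_ids),
                              list(base.st_matrix.column_ids), is_integer=True)
        out[depth] = SimulatedDataset(st, base.truth, base.cell_types,
                                      base.provenance)
        if nested:
            prev = vals
    return out


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``fractions``."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.sum() <= 0:
        raise ValueError("fractions must have positive sum")
    quota = fractions / fractions.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        remainder = quota - counts
        # ties resolved by lower index for determinism
        order = np.lexsort((np.arange(len(quota)), -remainder))
        counts[order[:short]] += 1
    return counts


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _recolor(u: np.ndarray, corr: float) -> np.ndarray:
    """Transform an (n, 2) sample so its empirical correlation is exactly
    ``corr`` (whiten by the empirical covariance, then recolor)."""
    z = (u - u.mean(axis=0)) / u.std(axis=0, ddof=0)
    cov = np.cov(z.T, ddof=0)
    chol = np.linalg.cholesky(cov)
    white = z @ np.linalg.inv(chol).T
    target = np.array([[1.0, corr], [corr, 1.0]])
    return white @ np.linalg.cholesky(target).T


def _rule_counts(
    rule: CompartmentRule,
    rho: float,
    cells_per_spot: int,
    rng: np.random.Generator,
    sigma: float = 0.35,
    calibration_iters: int = 6,
    calibration_tol: float = 0.005,
) -> tuple[list[str], np.ndarray]:
    """Integer cell counts per spot for one compartment rule.

    Co-localized pair fractions are bivariate logit-normal around their fixed
    means; free types split the residual mass by a symmetric Dirichlet; the
    fractions are realized as a largest-remainder split of ``cells_per_spot``
    cells.  Because quantization attenuates correlation, the latent pair
    correlation is calibrated by a short fixed-point loop (moment matching at
    generation time) so the *realized* integer proportions hit ``rho``.
    """
    n = rule.n_spots
    rule_types = list(rule.fixed) + [t for t in rule.free if t not in rule.fixed]
    pos = {t: i for i, t in enumerate(rule_types)}
    pair_base = {pair: rng.standard_normal((n, 2)) for pair in rule.pairs}
    paired = {t for pair in rule.pairs for t in pair}
    solo_jitter = {
        t: rng.standard_normal(n) for t in rule.fixed if t not in paired
    }
    free_w = (rng.dirichlet(np.ones(len(rule.free)), size=n)
              if rule.free else None)
    fixed_cols = [pos[t] for t in rule.fixed]

    def realize(latents: dict[tuple[str, str], float]) -> np.ndarray:
        fr = np.zeros((n, len(rule_types)))
        for pair, base in pair_base.items():
            a, b = pair
            u = _recolor(base, latents[pair])
            fr[:, pos[a]] = _sigmoid(_logit(rule.fixed[a]) + sigma * u[:, 0])
            fr[:, pos[b]] = _sigmoid(_logit(rule.fixed[b]) + sigma * u[:, 1])
        for t, u in solo_jitter.items():
            fr[:, pos[t]] = _sigmoid(_logit(rule.fixed[t]) + sigma * u)
        fixed_sum = fr[:, fixed_cols].sum(axis=1)
        over = fixed_sum > 0.95
        if over.any():
            scale = 0.95 / fixed_sum[over]
            for ci in fixed_cols:
                fr[over, ci] *= scale
        residual = 1.0 - fr[:, fixed_cols].sum(axis=1)
        if free_w is not None:
            for i, t in enumerate(rule.free):
                fr[:, pos[t]] += residual * free_w[:, i]
        else:
            fr /= fr.sum(axis=1, keepdims=True)
        counts = np.zeros((n, len(rule_types)), dtype=int)
        for s in range(n):
            counts[s] = _largest_remainder(fr[s], cells_per_spot)
        return counts

    latents = {pair: float(np.clip(rho, -0.98, 0.98)) for pair in rule.pairs}
    counts = realize(latents)
    for _ in range(calibration_iters):
        if not rule.pairs:
            break
        done = True
        for pair in rule.pairs:
            a, b = pair
            realized = np.corrcoef(counts[:, pos[a]], counts[:, pos[b]])[0, 1]
            if not np.isfinite(realized) or abs(realized) < 1e-6:
                continue
            if abs(realized - rho) > calibration_tol:
                latents[pair] = float(
                    np.clip(latents[pair] * rho / realized, -0.98, 0.98)
                )
                done = False
        if done:
            break
        counts = realize(latents)
    return rule_types, counts


def simulate_tme(
    sc: ExpressionMatrix,
    labels: CellTypeLabels,
    rules: list[CompartmentRule] | None = None,
    rho: float = 0.7,
    cells_per_spot: int = 10,
    umi_cap: int | None = UMI_CAP,
    umi_target: int = UMI_TARGET,
    seed: int = 0,
) -> SimulatedDataset:
    """Structured tumor-microenvironment simulation.

    Per compartment rule: the co-localized pair's fractions are drawn around
    their fixed means with the target correlation ``rho``; free types split
    the residual mass by a symmetric Dirichlet; all fractions are realized as
    an integer split of ``cells_per_spot`` cells by largest remainder, and
    that many cells of each type are sampled and aggregated.  Cell types not
    named in a rule have proportion exactly zero in that compartment.
    """
    if rules is None:
        rules = table1_rules()
    if not sc.is_integer:
        raise ValueError("simulation needs raw integer counts")
    labels.validate_against(sc)
    types = labels.cell_types
    needed = set()
    for r in rules:
        needed |= set(r.fixed) | set(r.free)
    missing = sorted(needed - set(types))
    if missing:
        raise ValueError(f"rules name cell types absent from labels: {missing}")
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[int]] = {t: [] for t in types}
    for i, c in enumerate(sc.column_ids):
        by_type[labels.assignments[c]].append(i)

    cols: list[np.ndarray] = []
    truth_cols: list[np.ndarray] = []
    regions: list[str] = []
    provenance: list[list[str]] = []
    t_idx = {t: i for i, t in enumerate(types)}
    for rule in rules:
        rule_types, count_matrix = _rule_counts(rule, rho, cells_per_spot, rng)
        for s in range(rule.n_spots):
            counts = count_matrix[s]
            chosen: list[int] = []
            for t, c in zip(rule_types, counts):
                if c == 0:
                    continue
                pool = by_type[t]
                if not pool:
                    raise ValueError(f"no cells of type {t!r} in the reference")
                replace = c > len(pool)
                if replace:
                    log.warning("type %r has %d cells < %d requested; sampling "
                                "with replacement", t, len(pool), c)
                chosen.extend(rng.choice(pool, size=c, replace=replace).tolist())
            col = _aggregate_spot(sc.values, np.array(chosen), rng,
                                  umi_cap, umi_target)
            cols.append(col)
            tv = np.zeros(len(types))
            for t, c in zip(rule_types, counts):
                tv[t_idx[t]] = c / cells_per_spot
            truth_cols.append(tv)
            regions.append(rule.region)
            provenance.append([sc.column_ids[i] for i in chosen])
    values = np.stack(cols, axis=1)
    truth = np.stack(truth_cols, axis=1)
    spot_ids = [f"{r}_{j}" for j, r in enumerate(regions)]
    st = ExpressionMatrix(values, list(sc.gene_ids), spot_ids, is_integer=True)
    return SimulatedDataset(st, truth, types, provenance, spot_region=regions)


DEFAULT_TYPE_NAMES = [
    "Malignant", "CD4T", "CD8T", "Tprolif", "B", "Plasma", "Mono/Macro",
    "Mast", "Endothelial", "Fibroblasts", "Myofibroblasts",
]


def make_block_fixture(
    n_types: int = 5,
    genes_per_type: int = 20,
    cells_per_type: int = 100,
    depth: int = 2000,
    noise: float = 0.05,
    background_genes: int = 100,
    seed: int = 0,
    type_names: list[str] | None = None,
) -> tuple[ExpressionMatrix, CellTypeLabels]:
    """Labeled single-cell matrix with block-structured marker genes.

    Each cell type owns a private block of ``genes_per_type`` high-rate
    marker genes; all types share ``background_genes`` background genes.
    Counts are multinomial draws of a Poisson(depth) total per cell.
    ``noise`` is the relative rate of off-type marker leakage (0 = perfectly
    private blocks).
    """
    if min(n_types, genes_per_type, cells_per_type, depth) <= 0:
        raise ValueError("all fixture dimensions must be positive")
    if type_names is None:
        type_names = (DEFAULT_TYPE_NAMES * ((n_types // 11) + 1))[:n_types]
        if n_types > 11:
            type_names = [f"type_{i:02d}" for i in range(n_types)]
    if len(type_names) != n_types:
        raise ValueError("type_names length must equal n_types")
    rng = np.random.default_rng(seed)
    n_genes = n_types * genes_per_type + background_genes
    gene_ids = [
        f"MK{t:02d}_{g:03d}" for t in range(n_types) for g in range(genes_per_type)
    ] + [f"BG_{g:03d}" for g in range(background_genes)]
    marker_weight, background_weight = 8.0, 1.0
    rates = np.full((n_genes, n_types), 0.0)
    for t in range(n_types):
        block = slice(t * genes_per_type, (t + 1) * genes_per_type)
        rates[: n_types * genes_per_type, t] = noise * marker_weight
        rates[block, t] = marker_weight
        rates[n_types * genes_per_type:, t] = background_weight
    probs = rates / rates.sum(axis=0, keepdims=True)
    cells = n_types * cells_per_type
    values = np.zeros((n_genes, cells), dtype=np.int64)
    assignments: dict[str, str] = {}
    col_ids = []
    for t in range(n_types):
        for c in range(cells_per_type):
            j = t * cells_per_type + c
            total = max(1, int(rng.poisson(depth)))
            values[:, j] = rng.multinomial(total, probs[:, t])
            cid = f"cell_{t:02d}_{c:04d}"
            col_ids.append(cid)
            assignments[cid] = type_names[t]
    matrix = ExpressionMatrix(values, gene_ids, col_ids, is_integer=True)
    return matrix, CellTypeLabels(assignments)
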