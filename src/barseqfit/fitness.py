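"""Gene fitness estimation from pooled-library barcode counts.

The estimator follows the standard pooled-fitness model: the fitness of an
insertion mutant (strain) is the log2 change in its depth-normalized
abundance between a harvest sample and the common T0 inoculum; gene
fitness is a count-weighted average over the gene's centrally inserted
strains, normalized first against a smoothed (running-median) baseline
along the chromosome — which absorbs replication-associated copy-number
trends — and then by subtracting the mode of the per-sample fitness
distribution, on the assumption that disrupting most genes has no fitness
effect. A moderated t-score (gene fitness over a variance-stabilized
standard deviation) says how reliably each fitness differs from zero.

Filters applied before estimation (all tunable via :class:`FitnessConfig`):
only insertions in the central 10%-90% of a gene are used, barcodes with
fewer than 3 T0 reads are ignored, and genes with fewer than 30 T0 reads
across their retained barcodes are not scored.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .containers import CountMatrix

_LN2_SQ_INV = 1.0 / np.log(2.0) ** 2


@dataclass(frozen=True)
class FitnessConfig:
    """Tunable parameters of the fitness pipeline.

    pseudocount
        Reads added to every strain count before taking log ratios.
        Guards zeros; kept small (0.1) because the bias it adds to a
        deleterious gene grows as log2(1 + psi/n_harvest) and harvest
        counts of strongly deleterious mutants are routinely below one
        read per strain-equivalent.
    min_t0_reads_per_barcode, min_t0_reads_per_gene
        T0 support filters (defaults 3 and 30 reads).
    central_only
        Restrict to insertions in the central 10%-90% of the gene.
    window
        Odd running-median window (in genes, chromosome order) for the
        position normalization.
    t_threshold
        |t| cutoff used downstream for significance calls.
    mode_grid_points
        Grid resolution of the kernel-density mode estimate.
    """

    pseudocount: float = 0.1
    min_t0_reads_per_barcode: int = 3
    min_t0_reads_per_gene: int = 30
    central_only: bool = True
    window: int = 251
    t_threshold: float = 3.0
    mode_grid_points: int = 512

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be > 0")
        if min(self.min_t0_reads_per_barcode, self.min_t0_reads_per_gene) < 0:
            raise ValueError("read thresholds must be >= 0")


def apply_filters(
    counts: CountMatrix, pool: pd.DataFrame, config: FitnessConfig | None = None
) -> tuple[pd.Index, pd.Index]:
    """Select the strains and genes that enter fitness estimation.

    Retained strains are (central) genic insertions with at least
    ``min_t0_reads_per_barcode`` T0 reads; scored genes are genes whose
    retained strains sum to at least ``min_t0_reads_per_gene`` T0 reads.
    Returns ``(retained barcodes, scored locus_tags)``.
    """
    config = config or FitnessConfig()
    t0 = counts.counts[counts.t0_sample]
    pool = pool.set_index("barcode")
    genic = pool["locus_tag"].fillna("") != ""
    ok = genic.copy()
    if config.central_only:
        ok &= pool["central"].astype(bool)
    t0_for_pool = t0.reindex(pool.index, fill_value=0)
    ok &= t0_for_pool >= config.min_t0_reads_per_barcode
    retained = pool.index[ok]
    gene_t0 = t0_for_pool[ok].groupby(pool.loc[ok, "locus_tag"]).sum()
    scored = gene_t0.index[gene_t0 >= config.min_t0_reads_per_gene]
    if len(scored) == 0:
        raise ValueError(
            "no genes pass the T0 filters "
            f"(retained strains: {len(retained)}; strongest gene T0 total: "
            f"{gene_t0.max() if len(gene_t0) else 0})"
        )
    return retained, pd.Index(scored, name="locus_tag")


def strain_fitness(n_h, n_0, N_h: float, N_0: float, pseudocount: float = 0.1):
    """log2 change in depth-normalized strain abundance vs T0.

    ``f = log2((n_h + psi)/(n_0 + psi)) - log2(N_h/N_0)`` with sample
    totals ``N_h``, ``N_0`` taken over the retained barcodes. Vectorized
    over array inputs.
    """
    n_h = np.asarray(n_h, dtype=float)
    n_0 = np.asarray(n_0, dtype=float)
    return np.log2((n_h + pseudocount) / (n_0 + pseudocount)) - np.log2(N_h / N_0)


def strain_weights(n_0, n_h):
    """Inverse-variance weights for the gene-level average.

    ``w = 1/(1/(1+n_0) + 1/(1+n_h))`` — the inverse of the Poisson
    delta-method variance of a log count ratio (up to the log-base
    constant), so well-sampled strains dominate the gene mean.
    """
    n_0 = np.asarray(n_0, dtype=float)
    n_h = np.asarray(n_h, dtype=float)
    return 1.0 / (1.0 / (1.0 + n_0) + 1.0 / (1.0 + n_h))


def gene_fitness_raw(f_s, w_s) -> float:
    """Weighted average of strain fitnesses for one gene."""
    f_s = np.asarray(f_s, dtype=float)
    w_s = np.asarray(w_s, dtype=float)
    if f_s.size == 0:
        raise ValueError("gene has no retained strains")
    if (w_s <= 0).any():
        raise ValueError("strain weights must be > 0")
    return float(np.sum(w_s * f_s) / np.sum(w_s))


def normalize_position(
    fitness: pd.Series,
    positions: pd.Series,
    scaffolds: pd.Series,
    circular: Mapping[str, bool] | bool = True,
    window: int = 251,
) -> pd.Series:
    """Subtract a running median of gene fitness along each chromosome.

    Genes are ordered by position within each scaffold and the median of
    the ``window`` genes centered on each is subtracted — circular wrap on
    circular scaffolds, truncated windows at the ends of linear ones.
    Scaffolds with fewer scored genes than the window fall back to the
    scaffold-wide median. Removes smooth positional trends (replication-
    fork copy-number bias) while leaving isolated gene effects intact.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    out = pd.Series(np.nan, index=fitness.index, dtype=float)
    half = window // 2
    for sc, idx in fitness.groupby(scaffolds).groups.items():
        sub = fitness.loc[idx]
        order = positions.loc[idx].sort_values(kind="stable").index
        vals = sub.loc[order].to_numpy(dtype=float)
        is_circ = circular.get(sc, True) if isinstance(circular, Mapping) else bool(circular)
        if len(vals) < window:
            baseline = np.full(len(vals), np.median(vals))
        elif is_circ:
            padded = np.concatenate([vals[-half:], vals, vals[:half]])
            baseline = _rolling_median(padded, window)[half : half + len(vals)]
        else:
            baseline = _rolling_median_truncated(vals, window)
        out.loc[order] = vals - baseline
    return out


def _rolling_median(vals: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(vals).rolling(window, center=True, min_periods=window).median().to_numpy()
    )


def _rolling_median_truncated(vals: np.ndarray, window: int) -> np.ndarray:
    return pd.Series(vals).rolling(window, center=True, min_periods=1).median().to_numpy()


def estimate_mode(values, grid_points: int = 512) -> float:
    """Argmax of a Gaussian-kernel density (Silverman bandwidth) on a grid."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("mode estimate needs at least 10 values")
    if np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def normalize_mode(values: pd.Series, grid_points: int = 512) -> pd.Series:
    """Center fitness values so the distribution mode sits at zero.

    Valid because disrupting most genes has little or no fitness effect,
    so the bulk of the distribution marks "no effect".
    """
    return values - estimate_mode(values.to_numpy(), grid_points)


def run_fitness(
    counts: CountMatrix,
    pool: pd.DataFrame,
    config: FitnessConfig | None = None,
    circular: Mapping[str, bool] | bool = True,
) -> pd.DataFrame:
    """Full pipeline: filters, strain and gene fitness, normalization, t-scores.

    Per replicate of each condition x timepoint the order is: T0 filters,
    strain fitness against the shared T0, weighted gene average, position
    normalization, mode normalization. Replicates are then averaged and a
    moderated t-score computed per gene:

    - per-replicate variance is the larger of the weighted strain spread
      ``sum(w^2 (f_s - f_g)^2) / (sum w)^2`` and a Poisson floor
      ``(1/ln2)^2 (1/(1+N0_g) + 1/(1+Nh_g))`` from the gene's read totals;
    - because every replicate is ratioed against the single shared T0
      sample, the T0 counting noise ``V0 = (1/ln2)^2 / (1+N0_g)`` is
      common to all replicates and does not average away; the variance of
      the replicate mean is therefore
      ``V_g = V0 + sum_r (V_r - V0) / R^2``;
    - moderation is one-sided: variances below the across-genes median are
      pulled halfway toward it, ``V_mod = max(V_g, (V_g + median(V_g))/2)``,
      stabilizing under-estimated variances without rewarding over-
      estimated ones; ``t = fbar / sqrt(V_mod)``.

    Returns one row per scored gene x condition x timepoint with columns
    ``locus_tag, condition, timepoint, fitness, t, n_strains, t0_reads,
    harvest_reads`` (mean over replicates).
    """
    config = config or FitnessConfig()
    retained, scored = apply_filters(counts, pool, config)
    pool_idx = pool.set_index("barcode")
    sub = pool_idx.loc[retained]
    in_scored = sub["locus_tag"].isin(scored)
    sub = sub[in_scored]
    strains = sub.index

    t0 = counts.counts.loc[strains, counts.t0_sample].to_numpy(dtype=float)
    N0 = float(t0.sum())
    gene_codes, gene_index = pd.factorize(sub["locus_tag"], sort=True)
    n_genes = len(gene_index)
    n_strains_per_gene = np.bincount(gene_codes, minlength=n_genes)
    gene_t0 = np.bincount(gene_codes, weights=t0, minlength=n_genes)

    # per-gene chromosome placement = position of its first retained insertion
    gene_meta = (
        sub.assign(_code=gene_codes)
        .groupby("_code")
        .agg(scaffold=("scaffold", "first"), pos=("pos", "min"))
    )
    gene_meta.index = gene_index  # codes are 0..n-1 in gene_index order

    harvest = counts.harvest_samples
    records = []
    for (cond, tp), grp in harvest.groupby(["condition", "timepoint"], sort=False):
        reps = list(grp.sort_values("replicate").index)
        R = len(reps)
        f_norm_reps = np.empty((R, n_genes))
        V_reps = np.empty((R, n_genes))
        gene_nh = np.empty((R, n_genes))
        for r, sample in enumerate(reps):
            nh = counts.counts.loc[strains, sample].to_numpy(dtype=float)
            Nh = float(nh.sum())
            f_s = strain_fitness(nh, t0, Nh, N0, config.pseudocount)
            w = strain_weights(t0, nh)
            wsum = np.bincount(gene_codes, weights=w, minlength=n_genes)
            f_g = np.bincount(gene_codes, weights=w * f_s, minlength=n_genes) / wsum
            resid = f_s - f_g[gene_codes]
            v_strain = (
                np.bincount(gene_codes, weights=(w * resid) ** 2, minlength=n_genes) / wsum**2
            )
            nh_g = np.bincount(gene_codes, weights=nh, minlength=n_genes)
            v_t0 = _LN2_SQ_INV / (1.0 + gene_t0)
            v_floor = v_t0 + _LN2_SQ_INV / (1.0 + nh_g)
            V_reps[r] = np.maximum(v_strain, v_floor)
            gene_nh[r] = nh_g

            raw = pd.Series(f_g, index=gene_index)
            adj = normalize_position(
                raw, gene_meta["pos"], gene_meta["scaffold"].astype(str),
                circular=circular, window=config.window,
            )
            f_norm_reps[r] = normalize_mode(adj, config.mode_grid_points).to_numpy()

        fbar = f_norm_reps.mean(axis=0)
        v_t0 = _LN2_SQ_INV / (1.0 + gene_t0)
        # shared-T0 noise is perfectly correlated across replicates
        V_g = v_t0 + (V_reps - v_t0).sum(axis=0) / R**2
        # moderation guards against under-estimated variances; genuinely
        # high variances are kept, not shrunk
        V_mod = np.maximum(V_g, 0.5 * (V_g + np.median(V_g)))
        t = fbar / np.sqrt(V_mod)
        records.append(
            pd.DataFrame(
                {
                    "locus_tag": gene_index,
                    "condition": cond,
                    "timepoint": tp,
                    "fitness": fbar,
                    "t": t,
                    "n_strains": n_strains_per_gene,
                    "t0_reads": gene_t0.astype(np.int64),
                    "harvest_reads": gene_nh.mean(axis=0),
                }
            )
        )
    return pd.concat(records, ignore_index=True)
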