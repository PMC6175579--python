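"""Competitive fitness of individual knockout mutants from CFU plate counts.

In a head-to-head competition a knockout mutant and the wild type are
co-inoculated 1:1; CFU counts at T0 and after one day give the mutant's
fraction of the population, and its fitness is the log2 fold change of
that fraction. A z-score across replicates asks whether the fitness is
below zero with a stated confidence (the assay used to validate pooled-
library fitness calls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as student_t

#: Plate-count table columns: one row per plate.
PLATE_COLUMNS = ["mutant", "replicate", "timepoint", "plate", "colonies", "dilution", "volume_ul"]


@dataclass(frozen=True)
class CompetitionResult:
    mutant: str
    fitness: tuple[float, ...]
    mean_fitness: float
    z: float
    significant: bool


def cfu_per_ml(colonies: float, dilution: float, volume_ul: float) -> float:
    """Colony-forming units per mL of the undiluted sample.

    ``CFU/mL = colonies / (dilution * volume_mL)``. Zero colonies returns
    0 (below detection); callers should treat it accordingly.
    """
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    if not 0 < dilution <= 1:
        raise ValueError("dilution must be in (0, 1]")
    if volume_ul <= 0:
        raise ValueError("plated volume must be > 0")
    return colonies / (dilution * volume_ul / 1000.0)


def competition_fitness(p0: float, p1: float) -> float:
    """log2 ratio of the mutant fraction after growth vs at T0.

    ``p`` is mutant CFU divided by total CFU (mutant + wild type).
    ``p1 = 0`` (mutant below detection) returns ``-inf``; ``p0 = 0`` is an
    input error — the competition was never seeded.
    """
    if not 0 < p0 <= 1:
        raise ValueError("T0 mutant fraction must be in (0, 1]")
    if not 0 <= p1 <= 1:
        raise ValueError("day-1 mutant fraction must be in [0, 1]")
    if p1 == 0:
        return float("-inf")
    return math.log2(p1 / p0)


def z_confidence(
    fitnesses, confidence: float = 0.95, test: str = "z"
) -> tuple[float, float, bool]:
    """Replicate-mean fitness, z-score and a one-sided below-zero call.

    ``z = mean / (sd / sqrt(R))`` with the sample standard deviation
    (R - 1 denominator); significant iff z falls below the one-sided
    critical value at ``confidence`` (-1.645 at 95% for the normal
    reference; ``test="t"`` uses the Student-t critical value at R - 1
    degrees of freedom instead). A single replicate yields an undefined
    z (NaN) and no call; zero spread with a nonzero mean yields an
    infinite z of the matching sign.
    """
    f = np.asarray(list(fitnesses), dtype=float)
    R = len(f)
    if R < 1:
        raise ValueError("need at least one replicate")
    mean = float(f.mean())
    if R == 1:
        return mean, float("nan"), False
    sd = float(f.std(ddof=1))
    if sd == 0:
        z = math.copysign(float("inf"), mean) if mean != 0 else 0.0
    else:
        z = mean / (sd / math.sqrt(R))
    if test == "z":
        crit = norm.ppf(1 - confidence)
    elif test == "t":
        crit = student_t.ppf(1 - confidence, df=R - 1)
    else:
        raise ValueError("test must be 'z' or 't'")
    significant = z <= crit
    return mean, z, bool(significant)


def analyze_competition(
    plates: pd.DataFrame, confidence: float = 0.95, test: str = "z"
) -> pd.DataFrame:
    """Per-mutant competition results from a plate-count table.

    ``plates`` has one row per plate with columns ``mutant, replicate,
    timepoint (T0|day1), plate (selective|total), colonies, dilution,
    volume_ul``: the selective plate counts the mutant (antibiotic
    marker), the non-selective plate the total population. Each
    (mutant, replicate) needs all four plates. Returns one row per
    mutant with the replicate fitnesses, mean, z and significance call.
    """
    missing = set(PLATE_COLUMNS) - set(plates.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    results = []
    for mutant, grp in plates.groupby("mutant", sort=True):
        fitnesses = []
        for rep, sub in grp.groupby("replicate"):
            fractions = {}
            for tp in ("T0", "day1"):
                cell = sub[sub["timepoint"] == tp]
                sel = cell[cell["plate"] == "selective"]
                tot = cell[cell["plate"] == "total"]
                if len(sel) != 1 or len(tot) != 1:
                    raise ValueError(
                        f"mutant {mutant!r} replicate {rep!r}: need exactly one "
                        f"selective and one total plate at {tp}"
                    )
                mutant_cfu = cfu_per_ml(*sel.iloc[0][["colonies", "dilution", "volume_ul"]])
                total_cfu = cfu_per_ml(*tot.iloc[0][["colonies", "dilution", "volume_ul"]])
                if total_cfu == 0:
                    raise ValueError(f"total CFU below detection for {mutant!r} rep {rep!r} {tp}")
                fractions[tp] = mutant_cfu / total_cfu
            fitnesses.append(competition_fitness(fractions["T0"], fractions["day1"]))
        mean, z, sig = z_confidence(fitnesses, confidence=confidence, test=test)
        results.append(
            {
                "mutant": mutant,
                "n_replicates": len(fitnesses),
                "mean_fitness": mean,
                "z": z,
                "significant": sig,
            }
        )
    return pd.DataFrame(results)
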