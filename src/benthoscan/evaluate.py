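"""Ground-truth evaluation of the pipeline on synthetic surveys.

These helpers run the abundance/hotspot pipeline on generated surveys and
score it against the generator's known truth: recovery of regional mean
abundances (and their East/West ratio), sensitivity of the LISA hotspot
classifier to planted enhanced intervals, and the counts-vs-area
decorrelation property of standardisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sampling, spatial, synthetic


def survey_abundance_matrix(config, unit_length_m: float = 100.0):
    """Generate a survey and push it through the standardisation stage."""
    records, detections, truth = synthetic.generate_survey(config)
    units, records = sampling.partition_units(records, unit_length_m)
    matrix = sampling.pool_and_standardise(
        units, records, detections, region_map=truth.region_of_dive
    )
    return matrix, truth


def regional_mean_estimates(matrix) -> dict:
    """Mean total abundance over sampling units, per region."""
    total = matrix.total_abundance()
    return {
        region: float(total.loc[sub.index].mean())
        for region, sub in matrix.units.groupby("region")
    }


def regional_recovery(seeds, config_fn=synthetic.default_config) -> pd.DataFrame:
    """Estimated vs true regional means and East/West ratio across seeds."""
    rows = []
    for seed in seeds:
        matrix, truth = survey_abundance_matrix(config_fn(seed=seed))
        est = regional_mean_estimates(matrix)
        rows.append(
            {
                "seed": seed,
                "est_east": est.get("East", np.nan),
                "est_west": est.get("West", np.nan),
                "true_east": truth.regional_mean_abundance.get("East", np.nan),
                "true_west": truth.regional_mean_abundance.get("West", np.nan),
            }
        )
    df = pd.DataFrame(rows)
    df["est_ratio"] = df["est_east"] / df["est_west"]
    df["true_ratio"] = df["true_east"] / df["true_west"]
    return df


def planted_hotspot_units(units: pd.DataFrame, truth) -> list:
    """Unit ids whose interval midpoint falls in a planted hotspot interval."""
    out = []
    for dive_id, intervals in truth.hotspot_intervals.items():
        if not intervals:
            continue
        sub = units[units["dive_id"] == dive_id]
        mids = 0.5 * (sub["start_m"] + sub["end_m"])
        out += [
            uid
            for uid, mid in zip(sub.index, mids)
            if any(a <= mid <= b for a, b in intervals)
        ]
    return out


def hotspot_sensitivity(
    seeds,
    config_fn=synthetic.hotspot_benchmark_config,
    k: int = 6,
    n_perm: int = 999,
    alpha: float = 0.05,
) -> float:
    """Fraction of planted hotspot units classified as hotspots, pooled over seeds."""
    detected = planted = 0
    for seed in seeds:
        matrix, truth = survey_abundance_matrix(config_fn(seed=seed))
        lisa = spatial.lisa_per_dive(matrix, k=k, n_perm=n_perm, seed=seed, alpha=alpha)
        cls = lisa.set_index("unit_id")["class"]
        for uid in planted_hotspot_units(matrix.units, truth):
            planted += 1
            detected += int(cls.get(uid) == "hotspot")
    if planted == 0:
        raise ValueError("survey has no planted hotspot intervals")
    return detected / planted


def decorrelation_summary(seeds, config_fn=synthetic.constant_intensity_config) -> pd.DataFrame:
    """Counts-vs-area and abundance-vs-area correlations on flat surveys."""
    rows = []
    for seed in seeds:
        matrix, _ = survey_abundance_matrix(config_fn(seed=seed))
        check = sampling.decorrelation_check(matrix)
        rows.append(
            {
                "seed": seed,
                "r_counts_area": float(check["r_counts_area"].mean()),
                "r_abundance_area": float(check["r_abundance_area"].mean()),
            }
        )
    return pd.DataFrame(rows)
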