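"""Longitudinal growth analysis of trait and weighing records.

Body weight is linearly interpolated between weighing dates so animals can
be compared at common ages; stage summaries aggregate trait means and SDs
over configurable age windows; growth ratios and the surface-to-volume
decay (a power law in body weight) quantify how shape changes as animals
grow. Quality gating follows the scanning practice: records scoring below
3 are excluded from surface-area and volume analyses, while their linear
traits remain usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import GrowthSummary, TraitRecord, WeighRecord
from .synthetic import reference_table

TRAITS = ("bw", "bsa", "volume", "hg", "wh", "cd", "hw", "kw")
GATED_TRAITS = ("bsa", "volume")  # require quality >= 3
MIN_QUALITY = 3


def interpolate_bw(records: list, target_ages: list) -> list:
    """Linear BW interpolation at target ages, per animal.

    Exact at the recorded ages; extrapolation outside an animal's recorded
    range is refused (mirrors a study design where only bracketed ages are
    comparable). Returned records are flagged ``interpolated`` unless the
    target age coincides with a weighing date.
    """
    out = []
    by_animal: dict = {}
    for r in records:
        by_animal.setdefault(r.animal_id, []).append(r)
    for animal, recs in by_animal.items():
        recs = sorted(recs, key=lambda r: r.age)
        ages = np.array([r.age for r in recs], dtype=float)
        if len(np.unique(ages)) != len(ages):
            raise ValueError(f"duplicate weighing ages for animal {animal}")
        if len(recs) < 2:
            raise ValueError(f"animal {animal} has fewer than 2 weighings")
        bws = np.array([r.bw for r in recs], dtype=float)
        for t in target_ages:
            if t < ages[0] or t > ages[-1]:
                raise ValueError(
                    f"age {t} outside recorded range [{ages[0]}, {ages[-1]}] "
                    f"for animal {animal}; extrapolation is not supported"
                )
            bw = float(np.interp(t, ages, bws))
            out.append(
                WeighRecord(
                    animal_id=animal,
                    age=float(t),
                    bw=bw,
                    interpolated=not np.any(np.isclose(ages, t)),
                )
            )
    return out


def average_daily_gain(records: list, window: tuple) -> float:
    """Mean BW gain (kg/day) between two ages, interpolating at endpoints."""
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError("window must have positive length")
    ends = interpolate_bw(records, [t0, t1])
    by_animal: dict = {}
    for r in ends:
        by_animal.setdefault(r.animal_id, {})[r.age] = r.bw
    gains = [(d[t1] - d[t0]) / (t1 - t0) for d in by_animal.values()]
    return float(np.mean(gains))


def default_stages(half_window_days: float = 15.2) -> dict:
    """Stage windows centred on the reference-table stage ages (±0.5 month)."""
    df = reference_table()
    return {
        row["stage"]: (row["age_days"] - half_window_days, row["age_days"] + half_window_days)
        for _, row in df.iterrows()
    }


def stage_summary(traits: list, weights: list, stages: dict | None = None) -> list:
    """Per-stage mean and sample SD (n-1) of every trait.

    Within a window, each animal contributes its visit nearest the window
    centre; BW comes from interpolation at that visit age. Surface area and
    volume are dropped from records below the quality gate. Stages with no
    records are omitted (with a warning), not an error; an SD at n=1 is
    reported as missing.
    """
    import logging

    log = logging.getLogger(__name__)
    if stages is None:
        stages = default_stages()
    summaries = []
    for label, (lo, hi) in stages.items():
        centre = 0.5 * (lo + hi)
        chosen: dict = {}
        for rec in traits:
            if lo <= rec.age <= hi:
                cur = chosen.get(rec.animal_id)
                if cur is None or abs(rec.age - centre) < abs(cur.age - centre):
                    chosen[rec.animal_id] = rec
        if not chosen:
            log.warning("stage %s: no records in [%s, %s]", label, lo, hi)
            continue
        rows = []
        for animal, rec in chosen.items():
            row = {"age": rec.age}
            for t in TraitRecord.TRAITS:
                v = rec.get(t)
                if t in GATED_TRAITS and rec.quality < MIN_QUALITY:
                    v = None
                row[t] = np.nan if v is None else v
            try:
                bw = interpolate_bw(
                    [w for w in weights if w.animal_id == animal], [rec.age]
                )[0].bw
            except ValueError:
                bw = np.nan
            row["bw"] = bw
            rows.append(row)
        df = pd.DataFrame(rows)
        means, sds = {}, {}
        for t in TRAITS:
            col = df[t].dropna()
            if len(col) == 0:
                continue
            means[t] = float(col.mean())
            sds[t] = float(col.std(ddof=1)) if len(col) > 1 else None
        summaries.append(
            GrowthSummary(
                stage=label,
                mean_age=float(df["age"].mean()),
                n=len(df),
                means=means,
                sds=sds,
            )
        )
    return summaries


def reference_summaries() -> list:
    """The bundled published stage table as GrowthSummary objects (SI units)."""
    df = reference_table()
    out = []
    for _, row in df.iterrows():
        means = {
            "bw": row["bw_kg"],
            "bsa": row["bsa_m2"],
            "volume": row["volume_m3"],
            "wh": row["wh_m"],
            "cd": row["cd_m"],
            "hg": row["hg_m"],
            "kw": row["kw_m"],
        }
        sds = {
            "bw": row["bw_sd"],
            "bsa": row["bsa_sd"],
            "volume": row["volume_sd"],
            "wh": row["wh_m_sd"],
            "cd": row["cd_m_sd"],
            "hg": row["hg_m_sd"],
            "kw": row["kw_m_sd"],
        }
        out.append(
            GrowthSummary(
                stage=row["stage"],
                mean_age=float(row["age_days"]),
                n=5,
                means={k: float(v) for k, v in means.items()},
                sds={k: float(v) for k, v in sds.items()},
            )
        )
    return out


def growth_ratio(summaries: list, trait: str, from_stage: str, to_stage: str) -> float:
    """Ratio of stage means, e.g. how many times volume grew from 2 to 20 months."""
    by = {s.stage: s for s in summaries}
    for st in (from_stage, to_stage):
        if st not in by:
            raise KeyError(f"stage {st!r} not present")
        if trait not in by[st].means:
            raise KeyError(f"trait {trait!r} missing in stage {st!r}")
    denom = by[from_stage].means[trait]
    if denom == 0:
        raise ZeroDivisionError(f"zero mean for {trait!r} at {from_stage!r}")
    return float(by[to_stage].means[trait] / denom)


@dataclass
class SurfaceVolumeFit:
    """Fitted decay of the surface-to-volume ratio with body weight.

    Power form: ratio = a * bw**(-b); isometric growth predicts b = 1/3.
    Exponential form (optional): ratio = a * exp(-k * bw).
    """

    a: float
    b: float
    form: str
    ratios: pd.DataFrame = field(default_factory=pd.DataFrame)
    warning: str | None = None


def surface_to_volume_curve(
    traits: list, weights: list, form: str = "power"
) -> SurfaceVolumeFit:
    """Fit the surface-to-volume ratio as a decaying function of BW.

    Pairs each quality-gated trait record (bsa and volume present) with the
    interpolated BW at its age; fits by least squares on the log scale for
    the power form, or log-linear for the exponential form. A non-positive
    decay exponent on growing animals is reported as a warning, not an
    error.
    """
    rows = []
    for rec in traits:
        if rec.quality < MIN_QUALITY or rec.bsa is None or rec.volume is None:
            continue
        try:
            bw = interpolate_bw(
                [w for w in weights if w.animal_id == rec.animal_id], [rec.age]
            )[0].bw
        except ValueError:
            continue
        rows.append(
            {
                "animal_id": rec.animal_id,
                "age": rec.age,
                "bw": bw,
                "ratio": rec.bsa / rec.volume,
            }
        )
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} valid (bsa, volume, bw) triples; need >= 3")
    df = pd.DataFrame(rows)
    if form == "power":
        if np.ptp(np.log(df["bw"])) < 1e-12:
            slope, logc = 0.0, float(np.log(df["ratio"]).mean())
        else:
            slope, logc = np.polyfit(np.log(df["bw"]), np.log(df["ratio"]), 1)
        a, b = float(np.exp(logc)), float(-slope)
    elif form == "exponential":
        if np.ptp(df["bw"]) < 1e-12:
            slope, logc = 0.0, float(np.log(df["ratio"]).mean())
        else:
            slope, logc = np.polyfit(df["bw"], np.log(df["ratio"]), 1)
        a, b = float(np.exp(logc)), float(-slope)
    else:
        raise ValueError("form must be 'power' or 'exponential'")
    warning = None
    if b <= 0:
        warning = "surface-to-volume ratio does not decay with BW (b <= 0)"
    return SurfaceVolumeFit(a=a, b=b, form=form, ratios=df, warning=warning)
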