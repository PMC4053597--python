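"""Synthetic prescription-registry generator with known ground truth.

Emulates the statistical structure the analysis assumes — an elderly
cohort (born 1905-1944) followed 2005-2010, age-dependent (Gompertz)
mortality, heterogeneous repeat dispensing of anxiolytics/hypnotics
with history from 2004 so washout periods are observable, a fracture
hazard multiplied by a known rate ratio on exposed days, a circadian
event-time mixture (about two thirds of fractures in daytime), and
half-missing clock times — so that every pipeline stage can be
exercised at desk scale against known generating parameters.

Default scales: 56% women, 23% ever-users of anxiolytics and 30% of
hypnotics, mean age about 73 at entry, roughly 4-5% cumulative
fracture incidence over follow-up.  The default cohort size (50,000)
is a desk-scale stand-in for a national cohort; no attempt is made to
reproduce any real cohort's absolute counts.

The fracture process is a first-event, piecewise-constant-hazard model:
on a day exposed to drug groups G the hazard is

    h(day) = h0(age) * [ P_day * prod_{g in G} rho_day_g
                         + P_night * prod_{g in G} rho_night_g ]

and the event's clock-time class is drawn from the correspondingly
tilted day/night mixture.  With rho_day = rho_night = rho this reduces
to a plain multiplicative rate ratio rho on exposed days, which is
exactly the estimand the SIR targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drug_classification import assign_groups
from .exposure import ExposurePolicy, merge_windows, windows_from_dispensings
from .registry_io import StudyConfig, to_day

__all__ = ["SimConfig", "SimulatedRegistry", "simulate_cohort",
           "simulate_dispensings", "simulate_fractures", "simulate_registry",
           "write_registry"]

_DEFAULT_SUBSTANCE_MENU = {
    # group -> [(substance, full ATC code, weight)]
    "anxiolytics_total": [
        ("oxazepam", "N05BA04", 0.55),
        ("diazepam", "N05BA01", 0.35),
        ("hydroxyzine", "N05BB01", 0.10),
    ],
    "hypnotics_total": [
        ("zopiclone", "N05CF01", 0.70),
        ("zolpidem", "N05CF02", 0.15),
        ("nitrazepam", "N05CD02", 0.10),
        ("melatonin", "N05CH01", 0.05),
    ],
}


@dataclass
class SimConfig:
    """Generating parameters; the seed fully determines the output.

    Hazards are annual and converted to daily internally.  Mortality
    and fracture baselines are Gompertz in attained age,
    ``h(a) = alpha * exp(beta * a)``.  ``rate_ratio`` holds the true
    overall exposure rate ratio per dispensing-model group;
    ``rate_ratio_day``/``rate_ratio_night`` override it per diurnal
    class when a class-specific effect is wanted.
    ``ever_user_age_coef`` (log-odds per year of age at entry) makes
    use prevalence age-dependent, to generate confounding by age.
    """

    n_persons: int = 50_000
    seed: int = 0
    female_fraction: float = 0.56
    birth_year_min: int = 1905
    birth_year_max: int = 1944
    birth_year_mean: float = 1932.2
    birth_year_sd: float = 8.9
    mortality_alpha: float = 5.5e-5
    mortality_beta: float = 0.09
    emigration_rate: float = 0.001
    ever_user_fraction: dict = field(
        default_factory=lambda: {"anxiolytics_total": 0.23, "hypnotics_total": 0.30}
    )
    ever_user_age_coef: float = 0.0
    substance_menu: dict = field(default_factory=lambda: dict(_DEFAULT_SUBSTANCE_MENU))
    ddd_choices: tuple = (10.0, 25.0, 50.0, 100.0)
    ddd_weights: tuple = (0.35, 0.35, 0.20, 0.10)
    prevalent_user_fraction: dict | float = field(
        default_factory=lambda: {"anxiolytics_total": 0.35, "hypnotics_total": 0.60}
    )
    refill_gap_median: dict | float = field(
        default_factory=lambda: {"anxiolytics_total": 110.0, "hypnotics_total": 45.0}
    )
    refill_gap_log_sd: float = 0.6
    fracture_alpha: float = 4.4e-6
    fracture_beta: float = 0.10
    rate_ratio: dict = field(
        default_factory=lambda: {"anxiolytics_total": 1.4, "hypnotics_total": 1.2}
    )
    rate_ratio_day: dict = field(default_factory=dict)
    rate_ratio_night: dict = field(default_factory=dict)
    p_day: float = 2.0 / 3.0
    p_time_known: float = 0.51
    policy: ExposurePolicy = field(default_factory=lambda: ExposurePolicy.ddd(1.0))

    def __post_init__(self):
        for p in (self.female_fraction, self.p_day, self.p_time_known):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for v in self.ever_user_fraction.values():
            if not 0 <= v <= 1:
                raise ValueError("ever_user_fraction values must lie in [0, 1]")
        if min(self.mortality_alpha, self.fracture_alpha) < 0:
            raise ValueError("hazard scales must be non-negative")
        missing = set(self.ever_user_fraction) - set(self.substance_menu)
        if missing:
            raise ValueError(f"substance_menu lacks groups {sorted(missing)}")

    def rho_day(self, group: str) -> float:
        return self.rate_ratio_day.get(group, self.rate_ratio.get(group, 1.0))

    def rho_night(self, group: str) -> float:
        return self.rate_ratio_night.get(group, self.rate_ratio.get(group, 1.0))

    def rho_overall(self, group: str) -> float:
        """Marginal exposed/unexposed rate ratio implied by the diurnal mixture."""
        return self.p_day * self.rho_day(group) + (1 - self.p_day) * self.rho_night(group)

    def ground_truth(self) -> dict:
        out = dataclasses.asdict(self)
        out["policy"] = {
            "mode": self.policy.mode,
            "fixed_days": self.policy.fixed_days,
            "pdd_factor": self.policy.pdd_factor,
        }
        out["rho_overall"] = {g: self.rho_overall(g) for g in self.rate_ratio}
        return out


@dataclass
class SimulatedRegistry:
    persons: pd.DataFrame
    dispensings: pd.DataFrame
    fractures: pd.DataFrame
    windows_by_group: dict
    ground_truth: dict


def _per_group(value, group: str) -> float:
    """Dispensing-model parameters may be a scalar or a per-group dict."""
    if isinstance(value, dict):
        return value[group]
    return float(value)


def _first_hit_year(rng, annual_p: np.ndarray) -> np.ndarray:
    """Index of the first year (column) a Bernoulli trial fires; -1 if none."""
    u = rng.random(annual_p.shape)
    hit = u < annual_p
    any_hit = hit.any(axis=1)
    idx = np.where(any_hit, hit.argmax(axis=1), -1)
    return idx


def simulate_cohort(cfg: SimConfig, study: StudyConfig, rng) -> pd.DataFrame:
    n = cfg.n_persons
    sex = np.where(rng.random(n) < cfg.female_fraction, "female", "male")

    by = np.rint(rng.normal(cfg.birth_year_mean, cfg.birth_year_sd, n))
    bad = (by < cfg.birth_year_min) | (by > cfg.birth_year_max)
    while bad.any():
        by[bad] = np.rint(rng.normal(cfg.birth_year_mean, cfg.birth_year_sd, bad.sum()))
        bad = (by < cfg.birth_year_min) | (by > cfg.birth_year_max)
    by = by.astype(np.int64)

    years = np.arange(study.study_start.year, study.study_end.year + 1)
    year_start = np.array([to_day(pd.Timestamp(y, 1, 1).date()) for y in years])
    year_len = np.r_[np.diff(year_start), study.study_end_day - year_start[-1] + 1]

    age = years[None, :] - by[:, None]
    p_die = 1 - np.exp(-cfg.mortality_alpha * np.exp(cfg.mortality_beta * age))
    die_idx = _first_hit_year(rng, p_die)
    die_off = rng.integers(0, year_len[np.maximum(die_idx, 0)])
    death_day = np.where(die_idx >= 0, year_start[np.maximum(die_idx, 0)] + die_off, -1)

    p_emig = np.full((n, len(years)), 1 - np.exp(-cfg.emigration_rate))
    em_idx = _first_hit_year(rng, p_emig)
    em_off = rng.integers(0, year_len[np.maximum(em_idx, 0)])
    emig_day = np.where(em_idx >= 0, year_start[np.maximum(em_idx, 0)] + em_off, -1)

    def _dates(day):
        out = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
        m = day >= 0
        out[m] = pd.to_datetime(day[m], unit="D")
        return out

    return pd.DataFrame(
        {
            "person_id": np.array([f"P{i:07d}" for i in range(n)], dtype=object),
            "sex": sex,
            "birth_year": by,
            "death_date": _dates(death_day),
            "emigration_date": _dates(emig_day),
        }
    )


def _segmented_cumsum(values: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each segment of the given lengths."""
    if len(values) == 0:
        return values
    cs = np.cumsum(values)
    offsets = np.r_[0, np.cumsum(counts)[:-1]]
    base = np.repeat(np.r_[0, cs[offsets[1:] - 1]] if len(counts) > 1 else [0], counts)
    return cs - base


def _censor_day(persons: pd.DataFrame, study: StudyConfig) -> np.ndarray:
    end = np.full(len(persons), study.study_end_day, dtype=np.int64)
    for col in ("death_date", "emigration_date"):
        d = persons[col]
        m = d.notna().to_numpy()
        if m.any():
            end[m] = np.minimum(end[m], d[m].values.astype("datetime64[D]").astype(np.int64))
    return end


def simulate_dispensings(cfg: SimConfig, persons: pd.DataFrame, study: StudyConfig, rng) -> pd.DataFrame:
    n = len(persons)
    age_entry = study.study_start.year - persons["birth_year"].to_numpy()
    mean_age = study.study_start.year - cfg.birth_year_mean
    censor = _censor_day(persons, study)

    frames = []
    for group in sorted(cfg.ever_user_fraction):
        base = cfg.ever_user_fraction[group]
        if base == 0:
            continue
        if cfg.ever_user_age_coef:
            logit = np.log(base / (1 - base)) + cfg.ever_user_age_coef * (age_entry - mean_age)
            p_user = 1 / (1 + np.exp(-logit))
        else:
            p_user = np.full(n, base)
        users = np.flatnonzero(rng.random(n) < p_user)
        nu = len(users)
        if nu == 0:
            continue

        menu = cfg.substance_menu[group]
        w = np.array([m[2] for m in menu], dtype=float)
        sub_idx = rng.choice(len(menu), size=nu, p=w / w.sum())

        gap_median = _per_group(cfg.refill_gap_median, group)
        gap_u = rng.lognormal(np.log(gap_median), cfg.refill_gap_log_sd, nu)
        # prevalent users were already on the drug before follow-up starts
        # (their first observed dispensing falls in the pre-study history
        # year); the rest start incident use during follow-up
        prevalent = rng.random(nu) < _per_group(cfg.prevalent_user_fraction, group)
        first = np.where(
            prevalent,
            rng.integers(study.history_start_day, study.study_start_day, nu),
            rng.integers(study.study_start_day, study.study_end_day + 1, nu),
        )
        lam = (study.study_end_day - first) / gap_u
        k = rng.poisson(lam)
        gaps = np.maximum(1, np.rint(rng.exponential(1.0, int(k.sum())) * np.repeat(gap_u, k)))
        refill_day = np.repeat(first, k) + _segmented_cumsum(gaps, k).astype(np.int64)

        day = np.r_[first, refill_day]
        person_row = np.r_[users, np.repeat(users, k)]
        user_row = np.r_[np.arange(nu), np.repeat(np.arange(nu), k)]
        keep = (day <= study.study_end_day) & (day <= censor[person_row])
        day, person_row, user_row = day[keep], person_row[keep], user_row[keep]

        wq = np.asarray(cfg.ddd_weights, dtype=float)
        n_ddd = rng.choice(np.asarray(cfg.ddd_choices, dtype=float), size=len(day), p=wq / wq.sum())

        subs = np.array([m[0] for m in menu], dtype=object)[sub_idx[user_row]]
        atcs = np.array([m[1] for m in menu], dtype=object)[sub_idx[user_row]]
        frames.append(
            pd.DataFrame(
                {
                    "person_id": persons["person_id"].to_numpy()[person_row],
                    "atc_code": atcs,
                    "substance": subs,
                    "dispense_date": pd.to_datetime(day, unit="D"),
                    "n_ddd": n_ddd,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["person_id", "atc_code", "substance", "dispense_date", "n_ddd"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["person_id", "dispense_date"], kind="stable").reset_index(drop=True)


def simulate_fractures(
    cfg: SimConfig,
    persons: pd.DataFrame,
    windows_by_group: dict,
    study: StudyConfig,
    rng,
) -> pd.DataFrame:
    """First hip-fracture events from the piecewise-constant hazard.

    ``windows_by_group`` must hold merged exposure windows (under the
    generating policy) for every group named in ``cfg.rate_ratio``.
    """
    n = len(persons)
    row_of_person = pd.Series(np.arange(n), index=persons["person_id"])
    by = persons["birth_year"].to_numpy(np.int64)
    fu_start = study.study_start_day
    censor = _censor_day(persons, study)

    years = np.arange(study.study_start.year, study.study_end.year + 1)
    year_start = np.array([to_day(pd.Timestamp(y, 1, 1).date()) for y in years])

    # breakpoint records: (person row, day, d_log_day, d_log_night)
    rec_p = [np.repeat(np.arange(n), len(years)), np.arange(n)]
    rec_d = [np.tile(year_start, n), censor + 1]
    rec_ld = [np.zeros(n * len(years)), np.zeros(n)]
    rec_ln = [np.zeros(n * len(years)), np.zeros(n)]

    for group in sorted(cfg.rate_ratio):
        win = windows_by_group.get(group)
        if win is None or len(win) == 0:
            continue
        rows = win["person_id"].map(row_of_person).to_numpy(np.int64)
        ws = np.maximum(win["start_day"].to_numpy(np.int64), fu_start)
        we = np.minimum(win["end_day"].to_numpy(np.int64), censor[rows])
        keep = ws <= we
        rows, ws, we = rows[keep], ws[keep], we[keep]
        ld, ln = np.log(cfg.rho_day(group)), np.log(cfg.rho_night(group))
        rec_p += [rows, rows]
        rec_d += [ws, we + 1]
        rec_ld += [np.full(len(rows), ld), np.full(len(rows), -ld)]
        rec_ln += [np.full(len(rows), ln), np.full(len(rows), -ln)]

    pidx = np.concatenate(rec_p)
    day = np.concatenate(rec_d).astype(np.int64)
    dld = np.concatenate(rec_ld)
    dln = np.concatenate(rec_ln)
    order = np.lexsort((day, pidx))
    pidx, day, dld, dln = pidx[order], day[order], dld[order], dln[order]

    sum_ld = np.cumsum(dld)  # balanced within each person, so no leakage
    sum_ln = np.cumsum(dln)

    m = len(day)
    same = np.zeros(m, dtype=bool)
    same[:-1] = pidx[1:] == pidx[:-1]
    nxt = np.empty(m, dtype=np.int64)
    nxt[:-1] = day[1:]
    nxt[-1] = day[-1]
    seg_end = np.minimum(nxt, censor[pidx] + 1)
    seg_len = np.where(same, np.clip(seg_end - day, 0, None), 0)

    seg_year = day.astype("datetime64[D]").astype("datetime64[Y]").astype(np.int64) + 1970
    age = seg_year - by[pidx]
    base = cfg.fracture_alpha * np.exp(cfg.fracture_beta * age) / 365.25
    mult = cfg.p_day * np.exp(sum_ld) + (1 - cfg.p_day) * np.exp(sum_ln)
    haz = base * mult
    contrib = seg_len * haz

    c = np.cumsum(contrib)
    firsts = np.r_[0, 1 + np.flatnonzero(pidx[1:] != pidx[:-1])]
    lasts = np.r_[firsts[1:] - 1, m - 1]
    c_before = c[firsts] - contrib[firsts]
    target = c_before + rng.exponential(1.0, n)
    hit = target <= c[lasts]

    idx = np.searchsorted(c, target[hit], side="left")
    into = target[hit] - (c[idx] - contrib[idx])
    offset = np.floor(into / haz[idx]).astype(np.int64)
    ev_day = np.minimum(day[idx] + np.clip(offset, 0, None), seg_end[idx] - 1)
    ev_day = np.minimum(ev_day, censor[pidx[idx]])
    ev_person = pidx[idx]

    pd_evt = cfg.p_day * np.exp(sum_ld[idx])
    pn_evt = (1 - cfg.p_day) * np.exp(sum_ln[idx])
    p_day_evt = pd_evt / (pd_evt + pn_evt)
    is_day = rng.random(len(ev_day)) < p_day_evt
    mins_day = 8 * 60 + rng.integers(0, 12 * 60, len(ev_day))
    m0 = rng.integers(0, 12 * 60, len(ev_day))
    mins_night = np.where(m0 < 4 * 60, 20 * 60 + m0, m0 - 4 * 60)
    minutes = np.where(is_day, mins_day, mins_night)
    known = rng.random(len(ev_day)) < cfg.p_time_known
    times = np.array(
        [f"{mm // 60:02d}:{mm % 60:02d}" if k else "" for mm, k in zip(minutes, known)],
        dtype=object,
    )

    return pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy()[ev_person],
            "event_date": pd.to_datetime(ev_day, unit="D"),
            "event_time": times,
            "time_known": known,
        }
    ).reset_index(drop=True)


def simulate_registry(cfg: SimConfig, study: StudyConfig | None = None) -> SimulatedRegistry:
    """Generate a full synthetic registry: persons, dispensings,
    fractures, the generating exposure windows, and the ground truth."""
    study = study or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    persons = simulate_cohort(cfg, study, rng)
    dispensings = simulate_dispensings(cfg, persons, study, rng)

    windows_by_group: dict = {}
    if len(dispensings):
        classified = assign_groups(dispensings)
        for group in sorted(cfg.rate_ratio):
            sub = classified[classified["group"] == group]
            windows_by_group[group] = merge_windows(
                windows_from_dispensings(sub, cfg.policy)
            )
    fractures = simulate_fractures(cfg, persons, windows_by_group, study, rng)
    return SimulatedRegistry(
        persons=persons,
        dispensings=dispensings,
        fractures=fractures,
        windows_by_group=windows_by_group,
        ground_truth=cfg.ground_truth(),
    )


def write_registry(reg: SimulatedRegistry, outdir) -> None:
    """Write persons.csv, dispensings.csv, fractures.csv and
    ground_truth.yaml to a directory."""
    from pathlib import Path

    import yaml

    from . import registry_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry_io.write_persons(reg.persons, outdir / "persons.csv")
    registry_io.write_dispensings(reg.dispensings, outdir / "dispensings.csv")
    registry_io.write_fractures(reg.fractures, outdir / "fractures.csv")
    gt = dict(reg.ground_truth)
    gt["substance_menu"] = {
        g: [list(x) for x in v] for g, v in gt.get("substance_menu", {}).items()
    }
    gt["ddd_choices"] = list(gt.get("ddd_choices", ()))
    gt["ddd_weights"] = list(gt.get("ddd_weights", ()))
    with open(outdir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(gt, fh, sort_keys=True)
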