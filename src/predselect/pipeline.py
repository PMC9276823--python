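"""End-to-end orchestration: simulate, validate, and run the analysis chain.

The interchange format is plain CSV (documented headers below), config is
YAML, and a fixed seed makes every run byte-reproducible.

Tables
------
fish.csv       id, site, year, source, sl, weight  (netted fish only carry
               measured SL/weight; consumed fish are reconstructed from
               otoliths and appear here without measurements)
otoliths.csv   id, host_id, host_kind, site, year, side, radius_um,
               n_increments, widths (semicolon list, µm)
squid.csv      id, site, year, ml, weight, stomach_weight, capture_time,
               lunar_illumination
sites.csv      site, year, date, tow_time, lunar_illumination, bottom_temp

Outputs: events.csv, screen.csv, fits.csv, trajectories.csv, run_log.yaml.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohorts import assign_cohorts, build_trajectory_matrix, compare_trajectories
from .feeding import EvacuationModel, SquidRecord, build_events
from .otolith import (
    Calibration,
    OtolithRead,
    back_calculate_sl,
    estimate_age,
    pair_otoliths,
    sl_to_weight,
)
from .rejection import screen_site, threshold_sl
from .selectivity import compare_models, fit_population
from .synthdata import (
    OtolithGrowthParams,
    PopulationParams,
    RetentionCurve,
    SelectionSpec,
    generate_otoliths,
    generate_population,
    sample_consumed,
    sample_net_catch,
)

__all__ = ["RunConfig", "simulate", "validate_tables", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, calibration and analysis settings for one pipeline run."""

    data_dir: Path
    out_dir: Path
    calibration: Calibration = field(default_factory=Calibration)
    evacuation: EvacuationModel = field(default_factory=EvacuationModel)
    retention: RetentionCurve = field(default_factory=RetentionCurve)
    boot_B: int = 2000
    seed: int = 0
    cohort_k: dict = field(default_factory=dict)  # year -> k

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "calibration" in raw:
            c = raw["calibration"]
            kw["calibration"] = Calibration(
                or_sl=tuple(c.get("or_sl", Calibration().or_sl)),
                allometry=tuple(c.get("allometry", Calibration().allometry)),
                hatch=tuple(c.get("hatch", Calibration().hatch)),
            )
        if "evacuation" in raw:
            kw["evacuation"] = EvacuationModel(**raw["evacuation"])
        if "retention" in raw:
            kw["retention"] = RetentionCurve(**raw["retention"])
        for key in ("boot_B", "seed"):
            if key in raw:
                kw[key] = raw[key]
        if "cohort_k" in raw:
            kw["cohort_k"] = {int(y): int(k) for y, k in raw["cohort_k"].items()}
        kw["data_dir"] = Path(raw.get("data_dir", "."))
        kw["out_dir"] = Path(raw.get("out_dir", "out"))
        kw.update(overrides)
        return cls(**kw)


# -- simulation --------------------------------------------------------------

DEFAULT_SIM = {
    "retention": {"l50": 25.0, "delta": 3.0},
    "otolith_noise_sd": 0.0,
    "sites": [
        {
            "name": "St.01",
            "year": 2008,
            "n_netted": 40,
            "n_consumed": 12,
            "n_stomachs": 30,
            "selection": {"kind": "growth", "half": -2.0, "width": 2.0},
            "population": {},
            "lunar_illumination": 40.0,
            "tow_time": "06:30",
            "date": "2008-05-20",
            "bottom_temp": 18.0,
        }
    ],
}


def simulate(sim_config: dict | None, seed: int, out_dir) -> dict:
    """Generate the four input tables for a synthetic survey.

    One population per site, a retention-biased net sample, a
    selection-weighted consumed sample distributed over squid stomachs, and
    left+right otoliths for every fish. Returns the table dict and writes
    CSVs to ``out_dir`` when given.
    """
    cfg = dict(DEFAULT_SIM, **(sim_config or {}))
    retention = RetentionCurve(**cfg["retention"])
    og = OtolithGrowthParams()
    calib = Calibration()
    root = np.random.SeedSequence(seed)
    fish_rows, oto_frames, squid_rows, site_rows = [], [], [], []
    for s_i, site in enumerate(cfg["sites"]):
        name, year = site["name"], int(site["year"])
        sub = root.spawn(4)
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) + s_i for s in sub]
        pp = PopulationParams(seed=seeds[0], **site.get("population", {}))
        pop = generate_population(pp)
        netted = sample_net_catch(pop, retention, site["n_netted"], seed=seeds[1])
        sel = site.get("selection", {"kind": "random"})
        spec = SelectionSpec(
            kind=sel["kind"],
            l50_or_e50=sel.get("half", 0.0),
            width=sel.get("width", 2.0),
        )
        consumed = sample_consumed(pop, spec, site["n_consumed"], seed=seeds[2], params=pp)

        rng = np.random.default_rng(seeds[3])
        prefix = f"{year}-{name}"
        for frame, source in ((netted, "netted"), (consumed, "consumed")):
            frame["fish_uid"] = [f"{prefix}-{source}-{i}" for i in range(len(frame))]

        # squid: mantle length / weight scaled so PPMR spans the tens range
        n_sq = site["n_stomachs"]
        ml = rng.uniform(60.0, 160.0, n_sq)
        sq_w = 3.2e-5 * ml**3.0 * np.exp(rng.normal(0, 0.1, n_sq))
        hosts = rng.choice(n_sq, size=len(consumed), replace=True)
        squid_ids = [f"{prefix}-sq-{i}" for i in range(n_sq)]
        prey_w = consumed["weight"].to_numpy()
        stomach_w = np.zeros(n_sq)
        for h, w in zip(hosts, prey_w):
            stomach_w[h] += w
        stomach_w *= rng.uniform(0.01, 0.59, n_sq)  # partial digestion
        for i in range(n_sq):
            squid_rows.append(
                {
                    "id": squid_ids[i],
                    "site": name,
                    "year": year,
                    "ml": round(ml[i], 1),
                    "weight": round(sq_w[i], 2),
                    "stomach_weight": round(stomach_w[i], 4) if stomach_w[i] > 0 else "",
                    "capture_time": site["tow_time"],
                    "lunar_illumination": site["lunar_illumination"],
                }
            )

        host_of = {
            fid: squid_ids[h] for fid, h in zip(consumed["fish_uid"], hosts)
        }
        for frame, source in ((netted, "netted"), (consumed, "consumed")):
            oto = generate_otoliths(
                frame.drop(columns="id").rename(columns={"fish_uid": "id"}),
                og,
                noise_sd=cfg["otolith_noise_sd"],
                seed=seeds[3] + (0 if source == "netted" else 1),
            )
            oto["host_kind"] = "fish" if source == "netted" else "squid"
            if source == "consumed":
                oto["host_id"] = oto["fish_id"].map(host_of)
            else:
                oto["host_id"] = oto["fish_id"]
            oto["site"] = name
            oto["year"] = year
            oto_frames.append(oto.rename(columns={"fish_id": "id"}))
            for _, f in frame.iterrows():
                fish_rows.append(
                    {
                        "id": f["fish_uid"],
                        "site": name,
                        "year": year,
                        "source": source,
                        "sl": round(f["sl"], 2) if source == "netted" else "",
                        "weight": round(f["weight"], 4) if source == "netted" else "",
                        "true_sl": round(f["sl"], 4),
                        "true_age": int(f["age"]),
                    }
                )
        site_rows.append(
            {
                "site": name,
                "year": year,
                "date": site.get("date", ""),
                "tow_time": site["tow_time"],
                "lunar_illumination": site["lunar_illumination"],
                "bottom_temp": site.get("bottom_temp", ""),
            }
        )

    tables = {
        "fish": pd.DataFrame(fish_rows),
        "otoliths": pd.concat(oto_frames, ignore_index=True)[
            ["id", "host_id", "host_kind", "site", "year", "side",
             "radius_um", "n_increments", "widths"]
        ],
        "squid": pd.DataFrame(squid_rows),
        "sites": pd.DataFrame(site_rows),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for nm, df in tables.items():
            df.to_csv(out / f"{nm}.csv", index=False)
    return tables


# -- validation --------------------------------------------------------------

def validate_tables(data_dir) -> list[str]:
    """Schema and range checks on the four input tables.

    Returns a list of human-readable error strings (empty when clean);
    each names the file, row and column at fault.
    """
    data_dir = Path(data_dir)
    errors: list[str] = []

    def need(df, name, cols):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            errors.append(f"{name}: missing columns {missing}")
        return not missing

    fish = pd.read_csv(data_dir / "fish.csv")
    if need(fish, "fish.csv", ["id", "site", "year", "source", "sl"]):
        for i, row in fish.iterrows():
            if row["source"] not in ("netted", "consumed"):
                errors.append(f"fish.csv row {i}: bad source {row['source']!r}")
            if row["source"] == "netted" and not (
                pd.notna(row["sl"]) and float(row["sl"]) > 0
            ):
                errors.append(f"fish.csv row {i}: column sl must be positive")

    oto = pd.read_csv(data_dir / "otoliths.csv")
    if need(oto, "otoliths.csv", ["id", "host_id", "side", "radius_um", "n_increments"]):
        for i, row in oto.iterrows():
            if row["side"] not in ("left", "right"):
                errors.append(f"otoliths.csv row {i}: side must be left/right")
            if not row["radius_um"] > 0:
                errors.append(f"otoliths.csv row {i}: column radius_um must be positive")
            if isinstance(row.get("widths"), str) and row["widths"]:
                cum = sum(float(w) for w in row["widths"].split(";"))
                if cum > 1.01 * row["radius_um"]:
                    errors.append(
                        f"otoliths.csv row {i}: cumulative widths {cum:.1f} µm "
                        f"exceed radius {row['radius_um']:.1f} µm (1% tolerance)"
                    )

    squid = pd.read_csv(data_dir / "squid.csv")
    if need(squid, "squid.csv", ["id", "site", "ml", "weight", "lunar_illumination"]):
        for i, row in squid.iterrows():
            if not row["ml"] > 0:
                errors.append(f"squid.csv row {i}: column ml must be positive")
            if not 0 <= row["lunar_illumination"] <= 100:
                errors.append(
                    f"squid.csv row {i}: lunar_illumination outside [0, 100]"
                )

    sites = pd.read_csv(data_dir / "sites.csv")
    need(sites, "sites.csv", ["site", "year"])
    return errors


# -- the analysis chain ------------------------------------------------------

def _reads_from_frame(df: pd.DataFrame) -> list[OtolithRead]:
    reads = []
    for _, row in df.iterrows():
        widths = ()
        if isinstance(row.get("widths"), str) and row["widths"]:
            widths = tuple(float(w) for w in row["widths"].split(";"))
        reads.append(
            OtolithRead(
                fish_or_squid_id=row["id"],
                side=row["side"],
                radius_capture=float(row["radius_um"]),
                increment_widths=widths,
                n_increments=int(row["n_increments"]),
            )
        )
    return reads


def _reconstruct_individuals(tables: dict, calib: Calibration):
    """Build per-individual records (age, SL, weight, trajectory) for both
    netted and consumed fish from the otolith table."""
    fish = tables["fish"]
    oto = tables["otoliths"]
    records, traj_rows, groups = [], [], {}
    # netted: measured SL, left otolith for age + trajectory
    netted = fish[fish["source"] == "netted"]
    sl_by_id = dict(zip(netted["id"], netted["sl"].astype(float)))
    left = oto[(oto["host_kind"] == "fish") & (oto["side"] == "left")]
    for read in _reads_from_frame(left):
        fid = read.fish_or_squid_id
        meta = fish.loc[fish["id"] == fid].iloc[0]
        sl = sl_by_id[fid]
        age = estimate_age(read.n_increments)
        records.append(
            {
                "id": fid, "site": meta["site"], "year": int(meta["year"]),
                "source": "netted", "age": age, "sl": sl,
                "weight": float(sl_to_weight(sl, calib)), "squid_id": None,
            }
        )
        groups[fid] = "netted"
        series = back_calculate_sl(read, sl, calib)
        for _, r in series.iterrows():
            traj_rows.append({"id": fid, "age": int(r["age"]), "sl": r["sl"]})
    # consumed: pair per stomach, reconstruct SL from the left radius
    stomach = oto[oto["host_kind"] == "squid"]
    for (squid_id, site, year), grp in stomach.groupby(["host_id", "site", "year"]):
        for j, ind in enumerate(pair_otoliths(_reads_from_frame(grp), calib)):
            lefts = [r for r in ind["reads"] if r.side == "left"]
            read = lefts[0] if lefts else ind["reads"][0]
            sl = ind["sl"]
            fid = f"{squid_id}-prey{j}"
            records.append(
                {
                    "id": fid, "site": site, "year": int(year),
                    "source": "consumed", "age": estimate_age(read.n_increments),
                    "sl": sl, "weight": float(sl_to_weight(sl, calib)),
                    "squid_id": squid_id,
                }
            )
            groups[fid] = "consumed"
            series = back_calculate_sl(read, sl, calib)
            for _, r in series.iterrows():
                traj_rows.append({"id": fid, "age": int(r["age"]), "sl": r["sl"]})
    return pd.DataFrame(records), pd.DataFrame(traj_rows), groups


def run_pipeline(config: RunConfig) -> dict:
    """Execute otolith -> feeding -> rejection -> selectivity -> cohorts.

    Writes events.csv, screen.csv, fits.csv, trajectories.csv and
    run_log.yaml to ``config.out_dir`` and returns the in-memory results.
    """
    errors = validate_tables(config.data_dir)
    if errors:
        raise ValueError("input validation failed:\n" + "\n".join(errors))
    data_dir = Path(config.data_dir)
    tables = {
        nm: pd.read_csv(data_dir / f"{nm}.csv")
        for nm in ("fish", "otoliths", "squid", "sites")
    }
    calib = config.calibration
    individuals, trajectories, groups = _reconstruct_individuals(tables, calib)

    # feeding
    squids = [
        SquidRecord(
            id=row["id"], site=row["site"], ml=float(row["ml"]),
            weight=float(row["weight"]),
            stomach_weight=float(row["stomach_weight"])
            if pd.notna(row.get("stomach_weight")) and row.get("stomach_weight") != ""
            else None,
            capture_time=str(row["capture_time"]),
            lunar_illumination=float(row["lunar_illumination"]),
        )
        for _, row in tables["squid"].iterrows()
    ]
    consumed_ind = individuals[individuals["source"] == "consumed"]
    prey_by_squid = {
        sq: list(zip(grp["sl"], grp["weight"]))
        for sq, grp in consumed_ind.groupby("squid_id")
    }
    events = build_events(squids, prey_by_squid, config.evacuation)
    events_df = pd.DataFrame(
        {
            "squid_id": ev.squid_id,
            "n_prey": len(ev.prey_sl),
            "prey_weight_total": round(sum(ev.prey_weight), 6),
            "dr_percent": None if ev.dr is None else round(ev.dr, 3),
            "duration_min": None if ev.duration_min is None else round(ev.duration_min, 1),
            "time_at_predation": ev.time_at_predation,
            "ppmr_min": round(min(ev.ppmr), 2),
            "ppmr_max": round(max(ev.ppmr), 2),
            "fresh_prey": ev.fresh_prey,
        }
        for ev in events
    )

    # rejection screen per site
    screen_rows = []
    flagged_sites = []
    for (site, year), grp in individuals.groupby(["site", "year"]):
        sq_w = tables["squid"].query("site == @site and year == @year")["weight"]
        thr = threshold_sl(sq_w.to_numpy(dtype=float), calib)
        scr = screen_site(
            grp.loc[grp["source"] == "netted", "sl"],
            grp.loc[grp["source"] == "consumed", "sl"],
            thr,
            site=(site, year),
        )
        if scr.flagged:
            flagged_sites.append((site, int(year)))
        screen_rows.append(
            {
                "site": site, "year": int(year), "threshold_sl": round(thr, 2),
                "alpha_n": round(scr.alpha_n, 1), "alpha_c": round(scr.alpha_c, 1),
                "expected_upper": round(scr.expected_upper, 1),
                "flagged": scr.flagged,
            }
        )
    screen_df = pd.DataFrame(screen_rows)

    # selectivity at site / year / all scopes
    fit_rows = []
    ok = individuals[
        ~individuals.apply(lambda r: (r["site"], r["year"]) in flagged_sites, axis=1)
    ]
    scopes = [(f"site:{site}:{year}", grp) for (site, year), grp in ok.groupby(["site", "year"])]
    scopes += [(f"year:{year}", grp) for year, grp in ok.groupby("year")]
    if ok["year"].nunique() > 1:
        scopes.append(("all", ok))
    for scope, grp in scopes:
        netted = grp[grp["source"] == "netted"]
        consumed = grp[grp["source"] == "consumed"]
        if len(netted) < 5 or len(consumed) < 5:
            continue
        pop = fit_population(netted, config.retention)
        cmpres = compare_models(
            pop, consumed, scope=scope, boot_B=config.boot_B, seed=config.seed,
            excluded_sites=tuple(flagged_sites),
        )
        row = {"scope": scope, "n_consumed": len(consumed), "selected": cmpres.selected}
        for kind, f in cmpres.fits.items():
            row[f"lnL_{kind}"] = round(f.loglik, 3)
            row[f"aic_{kind}"] = round(f.aic, 3)
            if f.boot_p is not None:
                row[f"p_{kind}"] = f.boot_p
                row[f"stars_{kind}"] = f.stars
        fit_rows.append(row)
    fits_df = pd.DataFrame(fit_rows)

    # cohorts and growth-trajectory comparison per year
    traj_out = trajectories.merge(
        individuals[["id", "site", "year", "source"]], on="id"
    )
    cohort_reports = {}
    for year, grp in individuals.groupby("year"):
        k = config.cohort_k.get(int(year), 1)
        labels = assign_cohorts(grp, k)
        cmap = dict(zip(grp["id"], labels))
        traj_out.loc[traj_out["year"] == year, "cohort"] = (
            traj_out.loc[traj_out["year"] == year, "id"].map(cmap)
        )
        for c in range(k):
            ids = {i for i, lab in cmap.items() if lab == c}
            sub = trajectories[trajectories["id"].isin(ids)]
            sub_groups = {i: groups[i] for i in ids}
            counts = pd.Series(list(sub_groups.values())).value_counts()
            if len(counts) < 2 or counts.min() < 3:
                continue
            matrix = build_trajectory_matrix(sub, sub_groups)
            try:
                cohort_reports[(int(year), c)] = compare_trajectories(matrix)
            except ValueError:
                continue

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events_df.to_csv(out / "events.csv", index=False)
    screen_df.to_csv(out / "screen.csv", index=False)
    fits_df.to_csv(out / "fits.csv", index=False)
    traj_out.to_csv(out / "trajectories.csv", index=False)
    log = {
        "predselect_version": __version__,
        "seed": config.seed,
        "boot_B": config.boot_B,
        "retention": {"l50": config.retention.l50, "delta": config.retention.delta},
        "evacuation": {
            "slope": config.evacuation.slope,
            "intercept": config.evacuation.intercept,
        },
        "calibration": {
            "or_sl": list(config.calibration.or_sl),
            "allometry": list(config.calibration.allometry),
            "hatch": list(config.calibration.hatch),
        },
        "flagged_sites": [list(s) for s in flagged_sites],
        "cohort_comparisons": {
            f"{y}-cohort{c}": {"wilks_lambda": r["wilks_lambda"], "p": r["p"]}
            for (y, c), r in cohort_reports.items()
        },
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return {
        "individuals": individuals,
        "events": events_df,
        "screen": screen_df,
        "fits": fits_df,
        "trajectories": traj_out,
        "cohort_reports": cohort_reports,
        "flagged_sites": flagged_sites,
    }
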