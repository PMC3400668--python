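"""End-to-end orchestration: synthesize -> analyze -> report.

One call, :func:`run_full_analysis`, takes a flat configuration (every
protocol constant lives there: 6 cm s^-1 velocity increment, 30-min steps,
r^2 > 0.95 QC, 0.75 mass exponent, 500 fps, alpha = 0.05) and produces the
full report bundle under a run directory: per-individual trait table,
site summaries, correlation / ANOVA / Duncan tables, shape-regression and
genetic-distance summaries, plus a provenance record.  Identical
configuration and seed give byte-identical outputs.

The synthetic population mirrors the study design: five sites (two paired
lower-reach, two paired middle-reach, one upper-reach main-stream site; the
upper-reach tributary cell is structurally empty), 6-8 female fish per site,
with tributary/upper-reach fish given higher true Ucrit, RMR, MMR and Uopt
and shallower cost-curve steepness, and fast-start parameters identical
across sites.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import faststart, io, morpho, popgen, respirometry, stats, swim, synth
from ._version import __version__
from .errors import SwimkitError

logger = logging.getLogger("swimkit.pipeline")

#: Per-site sample sizes of the emulated study design.
DEFAULT_N_PER_SITE = {"YJ": 6, "HK": 6, "SN": 8, "SD": 8, "DG": 7}

#: Site-level true means of the generated population.  Chosen so that
#: tributary and upper-reach fish swim faster and cheaper per unit speed
#: (higher Ucrit, RMR and Uopt; lower steepness) while escape performance is
#: uniform across sites.
SITE_TRUTH = {
    #        ucrit  rmr   beta   latency vmax  radius  FR    CPD_BD
    "YJ": dict(ucrit=52.0, rmr=140.0, beta=0.031, latency=12.0, vmax=1.42, radius=10.0, fr=5.31, cpd_bd=0.439),
    "HK": dict(ucrit=62.0, rmr=175.0, beta=0.024, latency=12.0, vmax=1.24, radius=11.0, fr=5.05, cpd_bd=0.427),
    "SN": dict(ucrit=50.0, rmr=150.0, beta=0.032, latency=12.0, vmax=1.35, radius=15.0, fr=4.40, cpd_bd=0.385),
    "SD": dict(ucrit=64.0, rmr=180.0, beta=0.023, latency=12.0, vmax=1.28, radius=14.0, fr=4.37, cpd_bd=0.383),
    "DG": dict(ucrit=60.0, rmr=185.0, beta=0.024, latency=12.0, vmax=1.25, radius=11.0, fr=4.39, cpd_bd=0.394),
}

TRAITS = ["ucrit", "mmr", "rmr", "beta", "uopt", "latency", "vmax", "turn_radius",
          "FR", "AR", "CPH", "CPD_BD"]
ECOLOGY = ["river_slope", "water_velocity", "temperature", "altitude",
           "predator_size", "predator_abundance", "dissolved_oxygen"]


@dataclass
class PipelineConfig:
    """Flat, auditable home of every protocol constant and generator setting."""

    seed: int = 1
    out_dir: str = "swimkit_run"
    n_per_site: dict = field(default_factory=lambda: dict(DEFAULT_N_PER_SITE))
    # swim-tunnel protocol
    delta_v: float = 6.0  # cm s^-1 per step
    period: float = 30.0  # min per step
    start_v: float = 6.0  # cm s^-1
    resp_volume: float = 3.5  # L
    o2_duration: float = 20.0  # min of closed phase
    o2_interval: float = 2.0  # min between O2 samples
    o2_noise_sd: float = 0.02  # mg L^-1
    r2_min: float = 0.95
    mass_exponent: float = 0.75
    # fast-start filming
    fps: float = 500.0
    stim_frame: int = 25
    n_frames: int = 150
    traj_noise_sd: float = 0.03  # mm
    # morphometrics
    n_landmarks: int = 17
    deformation_magnitude: float = 0.06
    landmark_noise_sd: float = 0.01
    n_perm: int = 499
    # genetics
    seq_length: int = 1140
    within_d: float = 0.006
    between_d: float = 0.012
    kappa: float = 2.0
    # statistics
    alpha: float = 0.05
    # individual variation (CV of true per-fish parameters around site means)
    individual_cv: float = 0.06

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Read a flat YAML config; absent keys keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key, val in data.items():
        if not hasattr(cfg, key):
            raise SwimkitError(f"unknown config key: {key}")
        setattr(cfg, key, val)
    return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise SwimkitError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapped
    return deco


@_stage("synthesize+physiology")
def _build_individuals(cfg: PipelineConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate every fish and run respirometry, Ucrit, fast-start and ratios."""
    sites = {s.site_id: s for s in synth.builtin_site_table()}
    rows = []
    speed_rows = []
    for site_id, n_fish in cfg.n_per_site.items():
        truth = SITE_TRUTH[site_id]
        for i in range(n_fish):
            fish_seed = int(rng.integers(0, 2**31 - 1))
            frng = np.random.default_rng(fish_seed)
            mass = 0.0055 * float(np.exp(frng.normal(0.0, 0.10)))
            body_length = float(frng.normal(8.1, 0.27))
            gt = synth.FishGroundTruth(
                site_id=site_id,
                mass=mass,
                body_length=body_length,
                true_rmr=truth["rmr"] * (1 + frng.normal(0, cfg.individual_cv)),
                true_beta=truth["beta"] * (1 + frng.normal(0, cfg.individual_cv)),
                true_ucrit=truth["ucrit"] * (1 + frng.normal(0, cfg.individual_cv)),
                true_latency=truth["latency"] * (1 + abs(frng.normal(0, 0.3))),
                true_vmax=truth["vmax"] * (1 + frng.normal(0, cfg.individual_cv)),
                true_turn_radius=truth["radius"] * (1 + frng.normal(0, cfg.individual_cv)),
                seed=fish_seed,
            )
            fish_id = f"{site_id}{i + 1:02d}"

            # Ucrit trial
            trial = synth.gen_ucrit_trial(gt.true_ucrit, cfg.delta_v, cfg.period, cfg.start_v)
            ucrit = swim.compute_ucrit(trial)

            # one closed-phase O2 trace per completed step
            records = []
            for speed, dur in trial.step_history:
                if dur < cfg.o2_duration:
                    continue  # closed phase does not fit into a cut-short step
                # whole-animal per-kg rate whose 1-kg standardization follows
                # the fish's true power curve
                mo2_true = (gt.true_rmr / mass ** (1 - cfg.mass_exponent)) * np.exp(
                    gt.true_beta * speed
                )
                trace = synth.gen_o2_trace(
                    mo2_true, cfg.resp_volume, mass, mass,
                    duration=cfg.o2_duration, interval=cfg.o2_interval,
                    noise_sd=cfg.o2_noise_sd,
                    seed=int(frng.integers(0, 2**31 - 1)), speed=speed,
                )
                rec = respirometry.analyze_trace(trace, cfg.r2_min, cfg.mass_exponent)
                records.append(rec)
            passing = respirometry.qc_filter(records, cfg.r2_min)
            points = swim.per_speed_mo2(passing)
            curve = swim.fit_power_curve(points)
            mmr = respirometry.extract_mmr(records, cfg.r2_min)
            for speed, mo2_std in points:
                speed_rows.append(
                    dict(fish_id=fish_id, site_id=site_id, speed=speed, mo2_std=mo2_std,
                         cot=swim.compute_cot(mo2_std, speed).cot)
                )

            # fast-start
            traj = synth.gen_fast_start_traj(
                cfg.stim_frame, gt.true_latency, gt.true_vmax, gt.true_turn_radius,
                fps=cfg.fps, n_frames=cfg.n_frames, noise_sd=cfg.traj_noise_sd,
                seed=int(frng.integers(0, 2**31 - 1)),
            )
            metrics = faststart.analyze_trajectory(traj)

            # direct body measurements -> ratios
            fr_true = truth["fr"] * (1 + frng.normal(0, 0.04))
            cpd_bd_true = truth["cpd_bd"] * (1 + frng.normal(0, 0.04))
            body_depth = body_length / fr_true
            cfh = 0.25 * body_length * (1 + frng.normal(0, 0.05))
            ar_true = 4.05 * (1 + frng.normal(0, 0.08))
            fin_area = cfh**2 / ar_true
            ratios = morpho.morpho_ratios(
                body_length, body_depth, cfh, fin_area, cpd_bd_true * body_depth
            )

            eco = sites[site_id]
            rows.append(
                dict(
                    fish_id=fish_id, site_id=site_id, reach=eco.reach, stream=eco.stream,
                    mass=mass, body_length=body_length,
                    ucrit=ucrit, mmr=mmr, rmr=curve.alpha, beta=curve.beta, uopt=curve.uopt,
                    latency=metrics.latency_ms, vmax=metrics.vmax_m_s,
                    turn_radius=metrics.turn_radius_mm,
                    FR=ratios.FR, AR=ratios.AR, CPH=ratios.CPH, CPD_BD=ratios.CPD_BD,
                    **{name: getattr(eco, name) for name in ECOLOGY},
                )
            )
    traits = pd.DataFrame(rows)
    per_speed = pd.DataFrame(speed_rows)
    return traits, per_speed


@_stage("morphometrics")
def _run_morphometrics(cfg: PipelineConfig, traits: pd.DataFrame, rng: np.random.Generator):
    covariate = traits["water_velocity"].to_numpy()
    covariate = (covariate - covariate.mean()) / covariate.std()
    sample = synth.gen_landmarks(
        n=len(traits), k=cfg.n_landmarks,
        deformation_magnitude=cfg.deformation_magnitude,
        noise_sd=cfg.landmark_noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        covariate=covariate,
    )
    aligned = morpho.gpa_align(sample.configs)
    scores = morpho.tps_partial_warps(aligned)
    reg = morpho.shape_regression(
        scores, covariate, n_perm=cfg.n_perm, seed=int(rng.integers(0, 2**31 - 1))
    )
    return sample, aligned, scores, reg


@_stage("popgen")
def _run_popgen(cfg: PipelineConfig, rng: np.random.Generator):
    labels = list(cfg.n_per_site)
    n_per_group = max(cfg.n_per_site.values())
    aln = synth.gen_sequences(
        groups=len(labels), n_per_group=n_per_group, length=cfg.seq_length,
        within_d=cfg.within_d, between_d=cfg.between_d, kappa=cfg.kappa,
        seed=int(rng.integers(0, 2**31 - 1)), group_labels=labels,
    )
    dm = popgen.pairwise_matrix(aln)
    summary = popgen.group_mean_distances(dm, aln.groups)
    return aln, dm, summary


@_stage("statistics")
def _run_stats(cfg: PipelineConfig, traits: pd.DataFrame, per_speed: pd.DataFrame):
    # site-level ecology correlations (n = 5 sites)
    site_means = traits.groupby("site_id").mean(numeric_only=True)
    corr_rows = []
    for trait in TRAITS:
        for eco in ECOLOGY:
            res = stats.pearson_with_p(site_means[eco], site_means[trait])
            corr_rows.append(dict(trait=trait, ecology=eco, r=res.r, n=res.n, p=res.p))
    correlations = pd.DataFrame(corr_rows)

    # two-way reach x stream ANOVA per trait (missing upper-tributary cell)
    anova_rows = []
    dropped: dict[str, list[str]] = {}
    for trait in TRAITS:
        res = stats.factorial_anova(traits, trait, ["reach", "stream"])
        dropped[trait] = res.dropped_contrasts
        for term, row in res.table.iterrows():
            anova_rows.append(
                dict(response=trait, term=term, df=int(row["df"]), F=row["F"], p=row["p"],
                     residual_df=res.residual_df)
            )
    anova2 = pd.DataFrame(anova_rows)

    # three-way speed x reach x stream on MO2 and COT
    long = per_speed.merge(traits[["fish_id", "reach", "stream"]], on="fish_id")
    long["speed"] = long["speed"].astype(str)
    anova3_rows = []
    for response in ["mo2_std", "cot"]:
        res = stats.factorial_anova(long, response, ["speed", "reach", "stream"])
        for term, row in res.table.iterrows():
            anova3_rows.append(
                dict(response=response, term=term, df=int(row["df"]), F=row["F"], p=row["p"],
                     residual_df=res.residual_df)
            )
    anova3 = pd.DataFrame(anova3_rows)

    # Duncan letters across sites for the headline traits
    duncan_rows = []
    for trait in ["ucrit", "mmr", "rmr", "beta", "uopt"]:
        res = stats.duncan_letters(traits["site_id"], traits[trait], alpha=cfg.alpha)
        for grp in res.means.index:
            duncan_rows.append(
                dict(response=trait, site_id=grp, mean=res.means[grp], letters=res.letters[grp])
            )
    duncan = pd.DataFrame(duncan_rows)
    return correlations, anova2, anova3, duncan, dropped


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Run the whole pipeline; returns a dict of output paths and key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("swimkit %s, seed %d, config %s", __version__, cfg.seed, cfg.config_hash())
        master = np.random.SeedSequence(cfg.seed)
        rngs = [np.random.default_rng(s) for s in master.spawn(3)]

        sites = synth.builtin_site_table()
        io.write_site_table(out / "sites.tsv", sites)

        traits, per_speed = _build_individuals(cfg, rngs[0])
        sample, aligned, scores, reg = _run_morphometrics(cfg, traits, rngs[1])
        aln, dm, gsummary = _run_popgen(cfg, rngs[2])
        correlations, anova2, anova3, duncan, dropped = _run_stats(cfg, traits, per_speed)

        float_fmt = "%.10g"
        traits.to_csv(out / "traits.tsv", sep="\t", index=False, float_format=float_fmt)
        per_speed.to_csv(out / "per_speed.tsv", sep="\t", index=False, float_format=float_fmt)
        traits.groupby("site_id").mean(numeric_only=True).to_csv(
            out / "site_summary.tsv", sep="\t", float_format=float_fmt
        )
        correlations.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format=float_fmt)
        anova2.to_csv(out / "anova_two_way.tsv", sep="\t", index=False, float_format=float_fmt)
        anova3.to_csv(out / "anova_three_way.tsv", sep="\t", index=False, float_format=float_fmt)
        duncan.to_csv(out / "duncan_letters.tsv", sep="\t", index=False, float_format=float_fmt)
        io.write_tps(out / "landmarks.tps", sample.configs)
        io.write_fasta(out / "sequences.fasta", aln)
        io.write_groups(out / "groups.tsv", aln)
        io.write_distance_matrix(out / "distance_matrix.tsv", dm.ids, dm.d)

        genetics = dict(
            overall_mean=gsummary.overall_mean,
            overall_min=gsummary.overall_min,
            overall_max=gsummary.overall_max,
            within={k: v for k, v in gsummary.within.items()},
        )
        shape = dict(F=reg.F, p=reg.p, df1=reg.df1, df2=reg.df2, n_perm=reg.n_perm)
        provenance = dict(
            swimkit_version=__version__,
            numpy_version=np.__version__,
            pandas_version=pd.__version__,
            seed=cfg.seed,
            config_hash=cfg.config_hash(),
            config=asdict(cfg),
            dropped_anova_contrasts=dropped,
        )
        with open(out / "shape_regression.json", "w") as fh:
            json.dump(shape, fh, indent=2, sort_keys=True)
        with open(out / "genetic_summary.json", "w") as fh:
            json.dump(genetics, fh, indent=2, sort_keys=True)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()

    return dict(
        out_dir=str(out),
        traits=traits,
        per_speed=per_speed,
        correlations=correlations,
        anova_two_way=anova2,
        anova_three_way=anova3,
        duncan=duncan,
        shape_regression=reg,
        genetic_summary=gsummary,
    )
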