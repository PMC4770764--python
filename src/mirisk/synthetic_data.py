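"""Synthetic cohort generator.

Emulates the data structure the analysis assumes: a miRNA matrix
(559 probes by default) over myeloma (MM), MGUS, pooled-normal (BMPC) and
cell-line (HMCL) samples, a matched mRNA matrix, planted group differences,
planted miRNA-to-mRNA correlation links, planted prognostic probes driving
exponential-hazard survival with uniform censoring, clinical risk indices,
aberration subgroups, and an independent validation cohort carrying a
global affine scale shift. Ground truth is returned for recovery tests.

All randomness flows from a single seed through named substreams, so every
artifact is reproducible independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from mirisk.datamodel import (
    ABERRATION_NAMES,
    ClinicalAnnotation,
    ExpressionMatrix,
    Flag,
    Group,
    PredictionTable,
    Scale,
    SurvivalOutcome,
    write_annotation,
    write_expression,
    write_prediction_table,
)
from mirisk.errors import ConfigError

DEFAULT_ABERRATION_PREVALENCE = {
    "t4_14": 0.15,
    "t11_14": 0.20,
    "del17p": 0.10,
    "gain1q21": 0.35,
    "del13q": 0.45,
    "hyperdiploid": 0.50,
}

DEFAULT_TOOLS = (
    "diana_microt",
    "miranda",
    "mirwalk",
    "mirdb",
    "pita",
    "rnahybrid",
    "targetscan",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: mixes the stream label into the seed."""
    h = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:8], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, h)))


@dataclass
class SimulationConfig:
    n_mirna_probes: int = 559
    n_mrna_probes: int = 5000
    n_mm: int = 62
    n_mgus: int = 7
    n_bmpc: int = 3
    n_hmcl: int = 20
    n_survival: int = 53          # MM samples with EFS/OS outcomes
    n_validation: int = 345
    n_de_probes: int = 40
    de_log2fc_range: tuple[float, float] = (0.44, 2.2)
    n_prognostic: int = 5
    prognostic_loghr: float = 0.7   # marginal log HR per SD of each planted probe
    prognostic_rho: float = 0.8     # squared loading of planted probes on the latent risk factor
    n_target_links: int = 8
    link_r: float = 0.7
    noise_sd: float = 1.0
    variance_prior_df: float = 4.0   # probe variances ~ scaled inv-chi-square
    baseline_log2: float = 9.0
    censor_rate: float = 0.3
    hmcl_shift_sd: float = 1.5
    validation_shift: float = 0.7    # global affine shift a*x + b of the validation cohort
    validation_slope: float = 1.05
    aberration_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_ABERRATION_PREVALENCE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_mirna_probes": self.n_mirna_probes,
            "n_mrna_probes": self.n_mrna_probes,
            "n_mm": self.n_mm,
            "n_mgus": self.n_mgus,
            "n_bmpc": self.n_bmpc,
            "n_hmcl": self.n_hmcl,
            "n_validation": self.n_validation,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.n_de_probes < 0 or self.n_de_probes > self.n_mirna_probes:
            raise ConfigError("n_de_probes must lie in [0, n_mirna_probes]")
        if not abs(self.link_r) < 1:
            raise ConfigError("|link_r| must be < 1")
        if not (0.0 < self.censor_rate < 1.0):
            raise ConfigError("censor_rate must lie in (0, 1)")
        if not (0.0 < self.prognostic_rho < 1.0):
            raise ConfigError("prognostic_rho must lie in (0, 1)")
        if self.n_survival > self.n_mm:
            raise ConfigError("n_survival cannot exceed n_mm")

    @property
    def n_samples(self) -> int:
        return self.n_mm + self.n_mgus + self.n_bmpc + self.n_hmcl


@dataclass
class CohortTruth:
    """Planted effects, plus the frozen probe-level parameters needed to
    generate further cohorts from the same population (private fields)."""

    de_probe_ids: dict[str, dict[str, float]]       # contrast -> {probe: log2FC}
    prognostic_ids: dict[str, float]                # probe -> marginal log HR (per SD)
    target_links: list[tuple[str, str, float, int]]  # (miRNA, mRNA, r, sign)
    aberration_assignments: dict[str, dict[str, str]]
    probe_mu: np.ndarray = field(repr=False, default=None)
    probe_sd: np.ndarray = field(repr=False, default=None)
    mrna_mu: np.ndarray = field(repr=False, default=None)
    mrna_sd: np.ndarray = field(repr=False, default=None)
    hmcl_shift: np.ndarray = field(repr=False, default=None)
    risk_index_probes: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "de_probe_ids": self.de_probe_ids,
            "prognostic_ids": self.prognostic_ids,
            "target_links": [list(t) for t in self.target_links],
            "aberration_assignments": self.aberration_assignments,
            "risk_index_probes": self.risk_index_probes,
        }


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[Group]]:
    ids, groups = [], []
    for prefix, n, grp in (
        ("MM", config.n_mm, Group.MM),
        ("MGUS", config.n_mgus, Group.MGUS),
        ("BMPC", config.n_bmpc, Group.BMPC),
        ("HMCL", config.n_hmcl, Group.HMCL),
    ):
        for k in range(1, n + 1):
            ids.append(f"{prefix}{k:03d}")
            groups.append(grp)
    return ids, groups


def simulate_survival(
    scores,
    loghr: float,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> list[SurvivalOutcome]:
    """Exponential proportional-hazards event times with uniform censoring.

    hazard_i = baseline_hazard * exp(loghr * score_i); the censoring window
    is calibrated numerically so the expected censored fraction matches
    ``censor_rate``.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ConfigError("scores must be finite")
    if not (0.0 < censor_rate < 1.0):
        raise ConfigError("censor_rate must lie in (0, 1)")
    if baseline_hazard <= 0:
        raise ConfigError("baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    hazards = baseline_hazard * np.exp(loghr * scores)
    t_event = rng.exponential(1.0 / hazards)

    # P(censored_i | c_max) = E[min(T_i / c_max, 1)] for C ~ U(0, c_max)
    def censored_fraction(c_max: float) -> float:
        return float(np.minimum(t_event / c_max, 1.0).mean())

    lo, hi = 1e-6, float(t_event.max()) * 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    c_max = 0.5 * (lo + hi)
    t_cens = rng.uniform(0.0, c_max, size=scores.size)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    time = np.maximum(time, 1e-9)
    return [SurvivalOutcome(time=float(t), event=bool(e)) for t, e in zip(time, event)]


def _draw_probe_params(config: SimulationConfig, rng, n_probes: int, base_sd_scale=1.0):
    mu = rng.normal(config.baseline_log2, 1.0, size=n_probes)
    d0 = config.variance_prior_df
    s2 = (config.noise_sd * base_sd_scale) ** 2 * d0 / rng.chisquare(d0, size=n_probes)
    return mu, np.sqrt(s2)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[ClinicalAnnotation], CohortTruth]:
    """Generate the profiling cohort: miRNA and mRNA log2 matrices, clinical
    annotations (with survival for the first ``n_survival`` MM samples), and
    the ground truth of all planted effects."""
    seed = config.seed
    sample_ids, groups = _sample_ids(config)
    n = len(sample_ids)
    mirna_probes = [f"mir-sim-{k + 1:03d}" for k in range(config.n_mirna_probes)]
    mrna_probes = [f"ps_{k + 1:05d}_at" for k in range(config.n_mrna_probes)]

    rng_probe = _rng(seed, "probe_params")
    probe_mu, probe_sd = _draw_probe_params(config, rng_probe, config.n_mirna_probes)
    mrna_mu, mrna_sd = _draw_probe_params(config, rng_probe, config.n_mrna_probes)

    # choose disjoint planted probe sets: DE, prognostic, linked, risk-index
    rng_plant = _rng(seed, "planting")
    n_special = config.n_de_probes + config.n_prognostic + config.n_target_links + 9
    if n_special > config.n_mirna_probes:
        raise ConfigError(
            f"planted probe demand {n_special} exceeds n_mirna_probes"
        )
    special = rng_plant.choice(config.n_mirna_probes, size=n_special, replace=False)
    pos = 0
    de_idx = special[pos:pos + config.n_de_probes]; pos += config.n_de_probes
    prog_idx = special[pos:pos + config.n_prognostic]; pos += config.n_prognostic
    link_idx = special[pos:pos + config.n_target_links]; pos += config.n_target_links
    index_idx = special[pos:pos + 9]

    lo, hi = config.de_log2fc_range
    de_mag = rng_plant.uniform(lo, hi, size=config.n_de_probes)
    de_sign = np.where(rng_plant.random(config.n_de_probes) < 0.5, -1.0, 1.0)
    de_fc = de_mag * de_sign

    hmcl_shift = _rng(seed, "hmcl").normal(0.0, config.hmcl_shift_sd,
                                           size=config.n_mirna_probes)

    def _make_mirna(ids, grps, stream: str) -> np.ndarray:
        r = _rng(seed, stream)
        x = probe_mu[:, None] + r.normal(0.0, 1.0, size=(config.n_mirna_probes, len(ids))) * probe_sd[:, None]
        is_mm = np.array([g is Group.MM for g in grps])
        is_hmcl = np.array([g is Group.HMCL for g in grps])
        # planted MM-vs-normal differences (MGUS gets half the shift)
        is_mgus = np.array([g is Group.MGUS for g in grps])
        for j, fc in zip(de_idx, de_fc):
            x[j, is_mm] += fc
            x[j, is_mgus] += fc / 2.0
        if is_hmcl.any():
            x[np.ix_(np.arange(config.n_mirna_probes), np.where(is_hmcl)[0])] += (
                hmcl_shift[:, None]
            )
        return x

    mirna_values = _make_mirna(sample_ids, groups, "mirna_noise")

    # prognostic probes load on a shared latent risk factor f ~ N(0,1):
    # z_p = sqrt(rho) f + sqrt(1-rho) eps, so each probe's marginal log HR per
    # SD is prognostic_loghr when the hazard uses loghr_eff * f below
    rho = config.prognostic_rho
    rng_risk = _rng(seed, "latent_risk")
    latent_f = rng_risk.normal(0.0, 1.0, size=n)
    eps = rng_risk.normal(0.0, 1.0, size=(config.n_prognostic, n))
    mirna_values[prog_idx, :] = probe_mu[prog_idx, None] + probe_sd[prog_idx, None] * (
        np.sqrt(rho) * latent_f[None, :] + np.sqrt(1.0 - rho) * eps
    )
    risk_score = latent_f
    loghr_eff = config.prognostic_loghr / np.sqrt(rho)

    # mRNA matrix with planted miRNA->mRNA links; linked mRNA probes get
    # inflated variance so they survive the upstream variance filter
    rng_mrna = _rng(seed, "mrna_noise")
    mrna_values = mrna_mu[:, None] + rng_mrna.normal(
        0.0, 1.0, size=(config.n_mrna_probes, n)
    ) * mrna_sd[:, None]
    link_targets = rng_plant.choice(config.n_mrna_probes,
                                    size=config.n_target_links, replace=False)
    link_signs = np.where(rng_plant.random(config.n_target_links) < 0.5, -1, 1)
    target_links: list[tuple[str, str, float, int]] = []
    sd_boost = 2.0 * float(np.quantile(mrna_sd, 0.95))
    mirna_sd_floor = 2.0 * float(np.quantile(probe_sd, 0.95))
    r_link = config.link_r
    for i, j, sgn in zip(link_idx, link_targets, link_signs):
        # re-draw the linked miRNA probe with a high-variance profile
        probe_sd[i] = max(probe_sd[i], mirna_sd_floor)
        noise = _rng(seed, f"link_{i}").normal(0.0, 1.0, size=n)
        mirna_values[i, :] = probe_mu[i] + probe_sd[i] * noise
        zx = (mirna_values[i, :] - mirna_values[i, :].mean()) / mirna_values[i, :].std()
        eps = _rng(seed, f"link_eps_{j}").normal(0.0, 1.0, size=n)
        mrna_sd[j] = max(mrna_sd[j], sd_boost)
        mrna_values[j, :] = mrna_mu[j] + mrna_sd[j] * (
            sgn * r_link * zx + np.sqrt(1.0 - r_link**2) * eps
        )
        target_links.append((mirna_probes[i], mrna_probes[j], r_link, int(sgn)))

    # risk indices as linear combinations of designated probes plus noise
    rng_idx = _rng(seed, "indices")
    index_names = ("gpi", "uams", "ifm")
    risk_index_probes: dict[str, list[str]] = {}
    index_values: dict[str, np.ndarray] = {}
    for k, name in enumerate(index_names):
        rows = index_idx[3 * k: 3 * k + 3]
        z = (mirna_values[rows, :] - mirna_values[rows, :].mean(axis=1, keepdims=True))
        z = z / mirna_values[rows, :].std(axis=1, keepdims=True)
        index_values[name] = z.sum(axis=0) + rng_idx.normal(0.0, 0.5, size=n)
        risk_index_probes[name] = [mirna_probes[r] for r in rows]

    # aberration subgroups for MM samples
    rng_ab = _rng(seed, "aberrations")
    aberrations: dict[str, dict[str, str]] = {}
    for sid, grp in zip(sample_ids, groups):
        if grp is Group.MM:
            aberrations[sid] = {
                a: (Flag.PRESENT if rng_ab.random() < config.aberration_prevalence.get(a, 0.0)
                    else Flag.ABSENT).value
                for a in ABERRATION_NAMES
            }
        else:
            aberrations[sid] = {a: Flag.UNKNOWN.value for a in ABERRATION_NAMES}

    # survival for the first n_survival MM samples
    mm_cols = [k for k, g in enumerate(groups) if g is Group.MM][: config.n_survival]
    efs = simulate_survival(
        risk_score[mm_cols], loghr=loghr_eff, baseline_hazard=0.03,
        censor_rate=config.censor_rate, seed=_rng(seed, "efs").integers(2**31),
    )
    osurv = simulate_survival(
        risk_score[mm_cols], loghr=loghr_eff, baseline_hazard=0.015,
        censor_rate=config.censor_rate, seed=_rng(seed, "os").integers(2**31),
    )
    efs_by_col = dict(zip(mm_cols, efs))
    os_by_col = dict(zip(mm_cols, osurv))

    rng_iss = _rng(seed, "iss")
    annotations: list[ClinicalAnnotation] = []
    for k, (sid, grp) in enumerate(zip(sample_ids, groups)):
        is_mm = grp is Group.MM
        annotations.append(
            ClinicalAnnotation(
                sample_id=sid,
                group=grp,
                aberrations={a: Flag(v) for a, v in aberrations[sid].items()},
                iss_stage=str(rng_iss.choice(["I", "II", "III"])) if is_mm else "unknown",
                b2m=float(np.exp(rng_iss.normal(1.2, 0.6))) if is_mm else None,
                gpi=float(index_values["gpi"][k]) if is_mm else None,
                uams_score=float(index_values["uams"][k]) if is_mm else None,
                ifm_score=float(index_values["ifm"][k]) if is_mm else None,
                efs=efs_by_col.get(k),
                os=os_by_col.get(k),
            )
        )

    truth = CohortTruth(
        de_probe_ids={
            "MM_vs_BMPC": {mirna_probes[j]: float(fc) for j, fc in zip(de_idx, de_fc)}
        },
        prognostic_ids={mirna_probes[j]: config.prognostic_loghr for j in prog_idx},
        target_links=target_links,
        aberration_assignments=aberrations,
        probe_mu=probe_mu,
        probe_sd=probe_sd,
        mrna_mu=mrna_mu,
        mrna_sd=mrna_sd,
        hmcl_shift=hmcl_shift,
        risk_index_probes=risk_index_probes,
    )
    mirna = ExpressionMatrix(mirna_probes, sample_ids, mirna_values, Scale.LOG2)
    mrna = ExpressionMatrix(mrna_probes, sample_ids, mrna_values, Scale.LOG2)
    return mirna, mrna, annotations, truth


def generate_validation_cohort(
    config: SimulationConfig, truth: CohortTruth
) -> tuple[ExpressionMatrix, list[ClinicalAnnotation]]:
    """Independent MM cohort drawn from the same probe population, with the
    same planted prognostic structure, then shifted by the configured global
    affine transform (exercises documentation-by-value transfer)."""
    seed = config.seed
    nv = config.n_validation
    ids = [f"VAL{k + 1:03d}" for k in range(nv)]
    mirna_probes = [f"mir-sim-{k + 1:03d}" for k in range(config.n_mirna_probes)]
    rng = _rng(seed, "validation_noise")
    x = truth.probe_mu[:, None] + rng.normal(
        0.0, 1.0, size=(config.n_mirna_probes, nv)
    ) * truth.probe_sd[:, None]
    # same latent-factor prognostic structure as the training cohort
    rho = config.prognostic_rho
    rng_risk = _rng(seed, "validation_latent_risk")
    latent_f = rng_risk.normal(0.0, 1.0, size=nv)
    prog_rows = [mirna_probes.index(p) for p in truth.prognostic_ids]
    eps = rng_risk.normal(0.0, 1.0, size=(len(prog_rows), nv))
    x[prog_rows, :] = truth.probe_mu[prog_rows, None] + truth.probe_sd[prog_rows, None] * (
        np.sqrt(rho) * latent_f[None, :] + np.sqrt(1.0 - rho) * eps
    )
    loghr_eff = config.prognostic_loghr / np.sqrt(rho)
    efs = simulate_survival(
        latent_f, loghr=loghr_eff, baseline_hazard=0.03,
        censor_rate=config.censor_rate, seed=_rng(seed, "validation_efs").integers(2**31),
    )
    osurv = simulate_survival(
        latent_f, loghr=loghr_eff, baseline_hazard=0.015,
        censor_rate=config.censor_rate, seed=_rng(seed, "validation_os").integers(2**31),
    )
    shifted = config.validation_slope * x + config.validation_shift
    matrix = ExpressionMatrix(mirna_probes, ids, shifted, Scale.LOG2)
    annotations = [
        ClinicalAnnotation(sample_id=s, group=Group.MM, efs=e, os=o)
        for s, e, o in zip(ids, efs, osurv)
    ]
    return matrix, annotations


def generate_prediction_table(
    true_targets: set[str],
    decoys: set[str],
    p_hit_true: float = 0.9,
    p_hit_decoy: float = 0.2,
    tool_names=DEFAULT_TOOLS,
    seed: int = 0,
) -> PredictionTable:
    """Gene-by-tool boolean calls: true targets get many positive calls
    (each tool fires with ``p_hit_true``), decoys few."""
    true_targets = set(map(str, true_targets))
    decoys = set(map(str, decoys))
    if true_targets & decoys:
        raise ConfigError(f"true/decoy sets overlap: {sorted(true_targets & decoys)[:5]}")
    rng = np.random.default_rng(seed)
    genes = sorted(true_targets) + sorted(decoys)
    n_tools = len(tool_names)
    calls = np.zeros((len(genes), n_tools), dtype=bool)
    for i, g in enumerate(genes):
        p = p_hit_true if g in true_targets else p_hit_decoy
        calls[i] = rng.random(n_tools) < p
    return PredictionTable(genes, list(tool_names), calls)


def write_fixture_set(outdir, config: SimulationConfig) -> None:
    """Emit the full fixture family as TSV plus a JSON truth file.

    Re-running with the same config/seed reproduces byte-identical files.
    """
    os.makedirs(str(outdir), exist_ok=True)
    mirna, mrna, annotations, truth = generate_cohort(config)
    val_matrix, val_annotations = generate_validation_cohort(config, truth)
    write_expression(mirna, os.path.join(str(outdir), "mirna.tsv"))
    write_expression(mrna, os.path.join(str(outdir), "mrna.tsv"))
    write_annotation(annotations, os.path.join(str(outdir), "annotations.tsv"))
    write_expression(val_matrix, os.path.join(str(outdir), "validation_mirna.tsv"))
    write_annotation(val_annotations, os.path.join(str(outdir), "validation_annotations.tsv"))
    # one prediction table per linked miRNA: its true target plus decoys
    decoy_pool = [p for p in mrna.probe_ids
                  if p not in {t[1] for t in truth.target_links}][:40]
    for k, (mir, target, _, _) in enumerate(truth.target_links):
        table = generate_prediction_table(
            {target}, set(decoy_pool), seed=config.seed + 1000 + k
        )
        safe = mir.replace("/", "_")
        write_prediction_table(
            table, os.path.join(str(outdir), f"predictions_{safe}.tsv")
        )
    with open(os.path.join(str(outdir), "truth.json"), "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    with open(os.path.join(str(outdir), "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
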