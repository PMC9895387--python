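"""End-to-end pre/post cohort analysis.

Composes the stages: signal conditioning -> microstate pipeline (subject
models, group maps, backfitting, parameters, transitions) -> network
rhythm energies (forward model, priors, ReML inversion, band energies) ->
repeated-measures statistics with Bonferroni-corrected post hocs.  The
run is deterministic given the configuration and master seed; per-stage
seeds are split from the master via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preproc
from .containers import EEGRecording
from .forward import SphereHeadModel, build_sphere_leadfield
from .inverse import (
    BandDefinition,
    band_energies,
    epoch_covariance,
    mesh_green_prior,
    reml_estimate,
)
from .mesh import make_icosphere_mesh, make_synthetic_atlas
from .metacriterion import optimal_k_metacriterion
from .microstate import (
    MicrostateModel,
    backfit,
    canonical_maps,
    compute_parameters,
    extract_gfp_peaks,
    group_maps_two_stage,
    kmeans_polarity_invariant,
    transition_probabilities,
)
from .stats import posthoc_paired, rm_anova_two_way
from .synth import Cohort

__all__ = ["PipelineConfig", "CohortResult", "run_cohort", "TRANSITION_PAIRS"]

#: The twelve ordered state pairs reported for a four-class segmentation.
TRANSITION_PAIRS = [
    (0, 1), (1, 0), (0, 2), (2, 0), (0, 3), (3, 0),
    (1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2),
]


@dataclass
class PipelineConfig:
    """All tunables of a cohort run; serializable to YAML."""

    # conditioning
    band_hz: tuple[float, float] = (0.5, 45.0)
    notch_hz: float | None = 50.0
    analysis_window_s: float = 180.0
    epoch_s: float = 2.0
    reject_uv: float = 100.0
    # microstates
    microstate_band_hz: tuple[float, float] = (2.0, 20.0)
    k: int | str = 4  # or "auto"
    k_range: tuple[int, int] = (2, 8)
    n_restarts: int = 20
    # network rhythms
    mesh_subdivisions: int = 2
    head_model: SphereHeadModel = field(default_factory=SphereHeadModel)
    green_sigma: float = 0.6
    bands: BandDefinition = field(default_factory=BandDefinition)
    # statistics
    alpha: float = 0.05
    run_network: bool = True
    #: "subject": one inversion per subject from pooled pre+post covariance
    #: (condition contrasts then reflect band energy, not operator shifts);
    #: "condition": separate inversion per recording.
    operator_scope: str = "subject"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.band_hz[0] < self.band_hz[1]):
            raise ValueError("invalid conditioning band")
        if not (0 < self.microstate_band_hz[0] < self.microstate_band_hz[1]):
            raise ValueError("invalid microstate band")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ValueError("k must be 'auto' or an integer >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["head_model"] = {
            "radii": list(self.head_model.radii),
            "conductivities": list(self.head_model.conductivities),
            "n_terms": self.head_model.n_terms,
        }
        d["bands"] = [list(b) for b in self.bands.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "head_model" in d and isinstance(d["head_model"], dict):
            hm = d["head_model"]
            d["head_model"] = SphereHeadModel(
                radii=tuple(hm["radii"]),
                conductivities=tuple(hm["conductivities"]),
                n_terms=int(hm.get("n_terms", 80)),
            )
        if "bands" in d and isinstance(d["bands"], list):
            d["bands"] = BandDefinition(tuple((n, float(a), float(b)) for n, a, b in d["bands"]))
        for key in ("band_hz", "microstate_band_hz", "k_range"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


@dataclass
class CohortResult:
    """Tables and test results of one cohort run."""

    parameters: pd.DataFrame  # subject, condition, state, duration/occurrence/coverage/gev
    transitions: pd.DataFrame  # subject, condition, pair, prob
    energies: pd.DataFrame | None  # subject, condition, network, band, energy
    anova: dict[str, pd.DataFrame]
    posthoc: dict[str, pd.DataFrame]
    flags: pd.DataFrame
    group_model: MicrostateModel
    manifest: dict


def _condition_microstate_input(rec: EEGRecording, cfg: PipelineConfig) -> EEGRecording:
    r = preproc.crop(rec, 0.0, min(rec.duration_s, cfg.analysis_window_s))
    r = preproc.bandpass_filter(r, *cfg.band_hz)
    if cfg.notch_hz:
        r = preproc.notch_filter(r, cfg.notch_hz)
    r = preproc.rereference_average(r)
    return preproc.bandpass_filter(r, *cfg.microstate_band_hz)


def _condition_network_input(rec: EEGRecording, cfg: PipelineConfig):
    r = preproc.crop(rec, 0.0, min(rec.duration_s, cfg.analysis_window_s))
    r = preproc.bandpass_filter(r, *cfg.band_hz)
    if cfg.notch_hz:
        r = preproc.notch_filter(r, cfg.notch_hz)
    r = preproc.rereference_average(r)
    ep = preproc.epoch_fixed_length(r, cfg.epoch_s)
    return preproc.reject_artifacts_amplitude(ep, cfg.reject_uv)


def run_cohort(cohort: Cohort, config: PipelineConfig | None = None) -> CohortResult:
    """Analyze a pre/post cohort end to end.

    Every subject must have both conditions.  Raises with the offending
    stage and subject on failure.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    subjects = sorted({s for s, _ in cohort.recordings})
    conditions = ("pre", "post")
    for s in subjects:
        for c in conditions:
            if (s, c) not in cohort.recordings:
                raise ValueError(f"subject {s} is missing condition {c!r}")

    root = np.random.SeedSequence(cfg.seed)
    ss_fit, ss_group, ss_auto = root.spawn(3)
    fit_rng = np.random.default_rng(ss_fit)

    # --- stage 1: per-subject microstate models on conditioned data
    peaks = {}
    conditioned = {}
    for s in subjects:
        for c in conditions:
            try:
                rec = _condition_microstate_input(cohort.recordings[(s, c)], cfg)
            except Exception as err:  # noqa: BLE001
                raise RuntimeError(f"preprocessing failed for subject {s}/{c}: {err}") from err
            conditioned[(s, c)] = rec
            peaks[(s, c)] = extract_gfp_peaks(rec)

    if cfg.k == "auto":
        votes = []
        auto_rng = np.random.default_rng(ss_auto)
        for s in subjects:
            for c in conditions:
                votes.append(
                    optimal_k_metacriterion(
                        peaks[(s, c)], range(cfg.k_range[0], cfg.k_range[1] + 1),
                        n_restarts=max(5, cfg.n_restarts // 2), seed=auto_rng,
                    )
                )
        v = np.sort(votes)
        k = int(v[(len(v) - 1) // 2])
    else:
        k = int(cfg.k)

    subject_models = []
    for s in subjects:
        for c in conditions:
            try:
                subject_models.append(
                    kmeans_polarity_invariant(
                        peaks[(s, c)], k, n_restarts=cfg.n_restarts, seed=fit_rng
                    )
                )
            except Exception as err:  # noqa: BLE001
                raise RuntimeError(f"microstate fit failed for subject {s}/{c}: {err}") from err

    group = group_maps_two_stage(
        subject_models, k, n_restarts=cfg.n_restarts,
        seed=np.random.default_rng(ss_group),
        canonical=canonical_maps(cohort.montage),
    )
    names = group.labels_by_class

    # --- stage 2: backfit and temporal parameters
    param_rows, trans_rows = [], []
    for s in subjects:
        for c in conditions:
            seg = backfit(conditioned[(s, c)], group)
            st = compute_parameters(seg, conditioned[(s, c)], group)
            for j in range(k):
                param_rows.append(
                    {
                        "subject": s, "condition": c, "state": names[j],
                        "duration_ms": st.duration_ms[j],
                        "occurrence_per_s": st.occurrence_per_s[j],
                        "coverage": st.coverage[j],
                        "gev": st.gev[j],
                    }
                )
            tm = transition_probabilities(seg, k=k)
            for i, j in TRANSITION_PAIRS if k == 4 else [
                (i, j) for i in range(k) for j in range(k) if i != j
            ]:
                trans_rows.append(
                    {
                        "subject": s, "condition": c,
                        "pair": f"{names[i]}->{names[j]}",
                        "prob": tm.probs[i, j],
                    }
                )
    parameters = pd.DataFrame(param_rows)
    transitions = pd.DataFrame(trans_rows)

    # --- stage 3: network band energies
    energies = None
    if cfg.run_network:
        mesh = make_icosphere_mesh(cfg.mesh_subdivisions, radius=0.8)
        atlas = make_synthetic_atlas(mesh)
        if cohort.leadfield is not None and cohort.leadfield.n_vertices == mesh.n_vertices:
            lead = cohort.leadfield
        else:
            lead = build_sphere_leadfield(cfg.head_model, cohort.montage, mesh)
        priors = mesh_green_prior(mesh, atlas, lead, sigma=cfg.green_sigma)
        energy_rows = []
        for s in subjects:
            eps = {c: _condition_network_input(cohort.recordings[(s, c)], cfg) for c in conditions}
            operator = None
            if cfg.operator_scope == "subject":
                covs, ns = [], 0
                for c in conditions:
                    covs.append(epoch_covariance(eps[c]))
                    kp = eps[c].kept()
                    ns += kp.shape[0] * kp.shape[2]
                res = reml_estimate(np.mean(covs, axis=0), lead, priors, n_samples=ns)
                operator = res.posterior_operator
            for c in conditions:
                tab = band_energies(eps[c], lead, priors, atlas, cfg.bands, operator=operator)
                df = tab.to_dataframe().reset_index(names="network").melt(
                    id_vars="network", var_name="band", value_name="energy"
                )
                df.insert(0, "condition", c)
                df.insert(0, "subject", s)
                energy_rows.append(df)
        energies = pd.concat(energy_rows, ignore_index=True)

    # --- stage 4: statistics
    anova, posthoc, flag_rows = {}, {}, []

    def _pivot(df, value, column):
        return df.pivot_table(index="subject", columns=["condition", column], values=value)

    for measure in ("duration_ms", "occurrence_per_s", "coverage"):
        wide = _pivot(parameters, measure, "state")
        states = sorted(parameters["state"].unique())
        arr = np.stack(
            [[wide[(c, st)].to_numpy() for st in states] for c in conditions]
        ).transpose(2, 0, 1)  # subjects x time x state
        anova[measure] = rm_anova_two_way(arr, "time", "state")
        pairs = [
            (st, wide[("post", st)].to_numpy(), wide[("pre", st)].to_numpy())
            for st in states
        ]
        ph = posthoc_paired(pairs, m=len(states))
        posthoc[measure] = ph
        for _, row in ph.iterrows():
            flag_rows.append(
                {
                    "family": measure, "name": row["comparison"],
                    "direction": "up" if row["mean_diff"] > 0 else "down",
                    "p": row["p_bonferroni"],
                    "significant": row["p_bonferroni"] < cfg.alpha,
                }
            )

    wide_t = _pivot(transitions, "prob", "pair")
    pair_names = [f"{names[i]}->{names[j]}" for i, j in TRANSITION_PAIRS] if k == 4 else sorted(
        transitions["pair"].unique()
    )
    arr = np.stack(
        [[wide_t[(c, p)].to_numpy() for p in pair_names] for c in conditions]
    ).transpose(2, 0, 1)
    anova["transition"] = rm_anova_two_way(arr, "time", "pair")
    ph = posthoc_paired(
        [(p, wide_t[("post", p)].to_numpy(), wide_t[("pre", p)].to_numpy()) for p in pair_names],
        m=len(pair_names),
    )
    posthoc["transition"] = ph
    for _, row in ph.iterrows():
        flag_rows.append(
            {
                "family": "transition", "name": row["comparison"],
                "direction": "up" if row["mean_diff"] > 0 else "down",
                "p": row["p_bonferroni"],
                "significant": row["p_bonferroni"] < cfg.alpha,
            }
        )

    if energies is not None:
        nets = list(dict.fromkeys(energies["network"]))
        for band in cfg.bands.names:
            sub = energies[energies["band"] == band]
            wide_e = _pivot(sub, "energy", "network")
            arr = np.stack(
                [[wide_e[(c, n)].to_numpy() for n in nets] for c in conditions]
            ).transpose(2, 0, 1)
            anova[f"energy_{band}"] = rm_anova_two_way(arr, "time", "network")
            ph = posthoc_paired(
                [(n, wide_e[("post", n)].to_numpy(), wide_e[("pre", n)].to_numpy()) for n in nets],
                m=len(nets),
            )
            posthoc[f"energy_{band}"] = ph
            for _, row in ph.iterrows():
                flag_rows.append(
                    {
                        "family": f"energy_{band}", "name": row["comparison"],
                        "direction": "up" if row["mean_diff"] > 0 else "down",
                        "p": row["p_bonferroni"],
                        "significant": row["p_bonferroni"] < cfg.alpha,
                    }
                )

    flags = pd.DataFrame(flag_rows)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_subjects": len(subjects),
        "k": k,
        "conditions": list(conditions),
    }
    return CohortResult(
        parameters=parameters,
        transitions=transitions,
        energies=energies,
        anova=anova,
        posthoc=posthoc,
        flags=flags,
        group_model=group,
        manifest=manifest,
    )


def write_result(result: CohortResult, out_dir) -> None:
    """Persist a run: CSV tables, group prototypes, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.parameters.to_csv(out / "microstate_parameters.csv", index=False)
    result.transitions.to_csv(out / "transition_probabilities.csv", index=False)
    if result.energies is not None:
        result.energies.to_csv(out / "network_band_energies.csv", index=False)
    for name, tab in result.anova.items():
        tab.to_csv(out / f"anova_{name}.csv")
    for name, tab in result.posthoc.items():
        tab.to_csv(out / f"posthoc_{name}.csv", index=False)
    result.flags.to_csv(out / "flags.csv", index=False)
    np.savetxt(out / "group_prototypes.csv", result.group_model.prototypes.T, delimiter=",")
    with open(out / "manifest.json", "w") as f:
        json.dump(result.manifest, f, indent=2, sort_keys=True)
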