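"""End-to-end pipelines on the default synthetic scenarios.

Two branches mirror the two halves of the analysis:

- the **kinetics branch** runs featurization (Gaussian state emissions) ->
  TICA -> k-means -> Markov state model -> implied timescales -> equilibrium
  resampling on a planted jump process, so the recovered transition matrix
  and timescales can be compared with the planted ones;
- the **structural branch** runs bundle-SASA classification -> conditional
  linchpin-RMSD distributions on the toy allosteric ensembles (wild-type,
  pathogenic-like and hyperactive-like planted scenarios), plus the
  label-model attribution benchmark.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ensemble, kinetics, structmetrics, synthdata

__all__ = [
    "KineticsPipelineResult",
    "AllostericPipelineResult",
    "run_kinetics_pipeline",
    "analyze_toy_scenario",
    "run_allosteric_pipeline",
    "run_default_scenario",
]

#: planted 4-state chain used by the default kinetics scenario: two slow
#: metastable pairs with a clear timescale separation
DEFAULT_PLANTED_T = np.array(
    [
        [0.95, 0.03, 0.01, 0.01],
        [0.03, 0.95, 0.01, 0.01],
        [0.01, 0.01, 0.90, 0.08],
        [0.01, 0.01, 0.08, 0.90],
    ]
)


@dataclass
class KineticsPipelineResult:
    model: kinetics.MSModel
    its_table: "object"
    sample: "object"
    planted_timescales: np.ndarray
    recovered_timescales: np.ndarray


def run_kinetics_pipeline(
    seed: int = 0,
    n_steps: int = 20_000,
    n_trajs: int = 5,
    lag: int = 1,
    n_clusters: int = 8,
    tica_dim: int = 4,
    n_samples: int = 30_000,
    T_true: np.ndarray | None = None,
    emission_sep: float = 6.0,
) -> KineticsPipelineResult:
    """Planted chain -> emissions -> TICA -> k-means -> MSM -> resampling.

    Emission means are orthogonal directions scaled to ``emission_sep`` (unit
    within-state SD), i.e. clearly metastable basins, so discretization error
    does not dominate the planted kinetics.
    """
    T = DEFAULT_PLANTED_T if T_true is None else np.asarray(T_true)
    k = T.shape[0]
    d = 5
    means = emission_sep * np.eye(k, d)
    covs = np.array([np.eye(d) for _ in range(k)])
    planted = synthdata.PlantedKinetics(T, means, covs, seed=seed)

    dtrajs_true = [
        synthdata.sample_markov_chain(T, n_steps, seed=seed + 101 + i)
        for i in range(n_trajs)
    ]
    feats = [
        synthdata.emit_features(dt, planted, seed=seed + 201 + i)
        for i, dt in enumerate(dtrajs_true)
    ]
    model_tica = kinetics.tica(feats, lag=lag, dim=tica_dim)
    Y = model_tica.transform(feats)
    _, dtrajs = kinetics.kmeans(Y, n_clusters, seed=seed)
    counts = kinetics.count_transitions(dtrajs, lag)
    msm = kinetics.estimate_msm(counts)
    its = kinetics.implied_timescales(dtrajs, lags=[1, 2, 5, 10], n_its=2)
    sample = kinetics.sample_equilibrium(msm, dtrajs, n=n_samples, seed=seed)

    ev_true = np.sort(np.abs(np.linalg.eigvals(T)))[::-1]
    planted_ts = -lag / np.log(ev_true[1:3])
    recovered_ts = msm.timescales(2)
    return KineticsPipelineResult(msm, its, sample, planted_ts, recovered_ts)


@dataclass
class AllostericPipelineResult:
    scenario: str
    cutoff: float
    classification: ensemble.BundleClassification
    conditional: ensemble.ConditionalSummary
    truth: "object"

    @property
    def primed_median(self) -> float:
        return float(self.conditional.summary.loc["primed", "median"])

    @property
    def collapsed_median(self) -> float:
        return float(self.conditional.summary.loc["collapsed", "median"])


def analyze_toy_scenario(
    scenario: str = "WT",
    seed: int = 0,
    n_frames: int = 5_000,
    n_points: int = 192,
    cutoff: float | None = None,
) -> AllostericPipelineResult:
    """Generate a planted toy ensemble and run the structural analysis chain.

    Bundle SASA per frame -> density-valley cutoff -> primed/collapsed
    classification -> linchpin RMSD conditioned on the bundle state.
    ``n_points`` is the sphere resolution for the per-frame SASA sweep
    (the toy burial contrast is far larger than the resolution error).
    """
    overrides = synthdata.DEFAULT_SCENARIOS[scenario]
    params = synthdata.ToyAllostericParams(n_frames=n_frames, seed=seed, **overrides)
    result = synthdata.generate_toy_allosteric(params)
    sasa_values = structmetrics.bundle_sasa_profile(
        result.trajectory, result.interface_residues, n_points=n_points
    )
    if cutoff is None:
        cutoff = ensemble.choose_cutoff(sasa_values)
    cls = ensemble.classify_bundle(sasa_values, cutoff)
    lin = structmetrics.linchpin_rmsd_profile(result.trajectory, result.reference)
    cond = ensemble.conditional_distributions(lin, cls.labels)
    return AllostericPipelineResult(scenario, cutoff, cls, cond, result.truth)


def run_allosteric_pipeline(seed: int = 0, n_frames: int = 5_000):
    """All three planted scenarios, analyzed with the wild-type cutoff."""
    wt = analyze_toy_scenario("WT", seed=seed, n_frames=n_frames)
    out = {"WT": wt}
    for scen in ("pathogenic", "hyperactive"):
        out[scen] = analyze_toy_scenario(
            scen, seed=seed, n_frames=n_frames, cutoff=wt.cutoff
        )
    return out


def run_default_scenario(seed: int = 0) -> dict[str, float]:
    """Full default pipeline; returns headline numbers from both branches."""
    kin = run_kinetics_pipeline(seed=seed)
    allo = run_allosteric_pipeline(seed=seed)
    Xa, Xb, informative, names = synthdata.generate_attribution_dataset(seed=seed)
    cfg = ensemble.LabelModelConfig(seed=seed)
    label_model = ensemble.train_label_model(Xa, Xb, cfg)
    ranking = ensemble.feature_label_correlation(
        np.vstack([Xa, Xb]), label_model.labels, names
    )
    return {
        "slowest_timescale_frames": float(kin.recovered_timescales[0]),
        "planted_slowest_timescale_frames": float(kin.planted_timescales[0]),
        "wt_primed_median_linchpin_rmsd": allo["WT"].primed_median,
        "wt_collapsed_median_linchpin_rmsd": allo["WT"].collapsed_median,
        "pathogenic_collapsed_median_linchpin_rmsd": allo["pathogenic"].collapsed_median,
        "hyperactive_collapsed_median_linchpin_rmsd": allo["hyperactive"].collapsed_median,
        "attribution_top_feature_is_planted": float(
            ranking.iloc[0]["feature"] == names[informative]
        ),
    }
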