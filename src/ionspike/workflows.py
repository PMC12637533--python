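"""End-to-end experiment workflows, reproducible from (config, seed).

``variant_excitability``: receptor-variant conductance scaling on a
morphologically detailed cell.  Ten synapses are placed either clustered
(localized, within a 50 μm sphere) or spread over the dendritic tree
(distributed); inputs are 10 Hz Poisson trains, either one shared train
(correlated) or independent trains (uncorrelated).  A calibration step
sets the global synaptic weight just below threshold so that the baseline
variant stays silent under uncorrelated input — gain-of-function variants
then reveal themselves as spiking.

``coupled_spike``: replica ensembles of the lattice-MC/cable loop under an
80 pA current clamp at 40/30/20 °C, aggregated as median and quartiles,
with spike-shape metrics and the cold/warm repolarization ratio.

``permeation``: conductance estimation from ion tracks by crossing
counting.  ``fixtures``: writes the synthetic input files consumed by the
other workflows.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cable import (HHMechanism, PassiveMechanism, advance, build_from_morphology,
                    detect_spikes, place_synapses)
from .coupling import CouplingConfig, repolarization_ratio, run_ensemble
from .lattice import EnergyParams
from .morphology import (generate_synthetic_morphology, sample_distributed,
                         sample_localized, write_swc)
from .permeation import (MembraneBounds, conductance_from_tracks,
                         count_crossings, generate_synthetic_tracks,
                         replicate_stats, tracks_from_csv, tracks_to_csv)
from .stimulus import CurrentClampSpec, make_inputs, trains_to_csv
from .synapses import BiExpParams, VariantTable

logger = logging.getLogger(__name__)

SPIKE_THRESHOLD_MV = -50.0


class CalibrationError(RuntimeError):
    """No synaptic weight separates the silent baseline from spiking variants."""


# ---------------------------------------------------------------------------
# variant excitability
# ---------------------------------------------------------------------------

DEFAULT_VARIANT_CFG = {
    "n_synapses": 10,
    "rate_hz": 10.0,
    "window_ms": 1000.0,
    "factors": [1, 3, 6, 30],
    "localized_radius_um": 50.0,
    "tree_depth": 5,
    "mean_segment_length_um": 40.0,
    "max_compartment_length_um": 40.0,
    "dt_ms": 0.025,
    "weight_bounds": [1e-3, 2.0],
    "weight_margin": 0.9,
    "region": "dendrite",
}


def _variant_setup(cfg: dict, seed: int):
    """Morphology, synapse layouts and spike trains shared across the grid."""
    seq = np.random.SeedSequence(seed)
    s_morph, s_loc, s_dist, s_corr, s_unc = seq.spawn(5)
    morph = generate_synthetic_morphology(
        "random_binary_tree", depth=cfg["tree_depth"],
        mean_segment_length=cfg["mean_segment_length_um"],
        rng_seed=np.random.default_rng(s_morph))
    sites = {
        "localized": sample_localized(
            morph, cfg["n_synapses"], radius=cfg["localized_radius_um"],
            region=cfg["region"], rng_seed=np.random.default_rng(s_loc)),
        "distributed": sample_distributed(
            morph, cfg["n_synapses"], region=cfg["region"],
            rng_seed=np.random.default_rng(s_dist)),
    }
    window = (0.0, cfg["window_ms"])
    trains = {
        "correlated": make_inputs(cfg["n_synapses"], cfg["rate_hz"], window,
                                  correlated=True, rng_seed=s_corr),
        "uncorrelated": make_inputs(cfg["n_synapses"], cfg["rate_hz"], window,
                                    correlated=False, rng_seed=s_unc),
    }
    return morph, sites, trains


def _run_condition(morph, sites, trains, cfg, factor, weight):
    """One simulated cell; returns (spike times, trace)."""
    model, seg_map = build_from_morphology(
        morph, max_compartment_length=cfg["max_compartment_length_um"],
        mechanism_map={"soma": HHMechanism(), "default": PassiveMechanism()})
    params = BiExpParams(g0=3.5 * factor, weight=weight)
    place_synapses(model, seg_map, sites, params, trains)
    trace = advance(model, dt=cfg["dt_ms"], t_stop=cfg["window_ms"])
    spikes = detect_spikes(trace, threshold=SPIKE_THRESHOLD_MV)
    return spikes, trace


def calibrate_weight(morph, sites, trains, cfg) -> float:
    """Bisect the synaptic weight so the baseline variant sits just below
    the spike threshold under uncorrelated input (both placements silent)."""

    def baseline_max_vm(w):
        worst = -np.inf
        for placement in ("localized", "distributed"):
            _, tr = _run_condition(morph, sites[placement],
                                   trains["uncorrelated"], cfg, 1.0, w)
            worst = max(worst, float(tr.trace().max()))
        return worst

    lo, hi = cfg["weight_bounds"]
    if baseline_max_vm(lo) >= SPIKE_THRESHOLD_MV:
        raise CalibrationError(
            f"baseline already crosses {SPIKE_THRESHOLD_MV} mV at the minimum "
            f"weight {lo}; no silent baseline exists in the search range")
    if baseline_max_vm(hi) < SPIKE_THRESHOLD_MV:
        # the whole range is silent for the baseline: use the top of the range
        logger.info("baseline silent across the weight range; using upper bound")
        return hi * cfg["weight_margin"]
    for _ in range(20):
        mid = np.sqrt(lo * hi)
        if baseline_max_vm(mid) < SPIKE_THRESHOLD_MV:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.05:
            break
    return lo * cfg["weight_margin"]


def variant_excitability(config: dict | None = None, seed: int = 0,
                         outdir: str | Path | None = None) -> dict:
    """Run the variant × placement × correlation grid; returns a results dict
    with the calibrated weight and a spike-count table."""
    cfg = {**DEFAULT_VARIANT_CFG, **(config or {})}
    morph, sites, trains = _variant_setup(cfg, seed)
    weight = calibrate_weight(morph, sites, trains, cfg)
    logger.info("calibrated synaptic weight: %.4g", weight)

    rows = []
    traces = {}
    for factor in cfg["factors"]:
        for placement in ("localized", "distributed"):
            for corr in ("correlated", "uncorrelated"):
                spikes, trace = _run_condition(
                    morph, sites[placement], trains[corr], cfg, factor, weight)
                rows.append({"factor": factor, "placement": placement,
                             "correlation": corr, "spike_count": len(spikes)})
                traces[(factor, placement, corr)] = trace
    table = pd.DataFrame(rows)
    result = {"weight": weight, "spike_counts": table, "traces": traces,
              "seed": seed, "config": cfg}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "spike_counts.csv", index=False)
        for (factor, placement, corr), tr in traces.items():
            tr.to_csv(outdir / f"trace_f{factor}_{placement}_{corr}.csv")
        _write_manifest(outdir, "variant_excitability", cfg, seed,
                        extra={"weight": weight})
    return result


# ---------------------------------------------------------------------------
# coupled spike
# ---------------------------------------------------------------------------

DEFAULT_COUPLED_CFG = {
    "temperatures_c": [40.0, 30.0, 20.0],
    # recording window per temperature: sized to the slower channel kinetics
    # at lower temperature so the full repolarization is captured
    "duration_ms": {40.0: 150.0, 30.0: 350.0, 20.0: 650.0},
    "n_replicas": 100,
    "clamp_pA": 80.0,
    "clamp_onset_ms": 5.0,
    "clamp_duration_ms": 10.0,
    "write_traces": False,
}


def coupled_spike(config: dict | None = None, seed: int = 0,
                  outdir: str | Path | None = None,
                  params: EnergyParams | None = None) -> dict:
    """Replica ensembles of the coupled run over the temperature grid."""
    cfg = {**DEFAULT_COUPLED_CFG, **(config or {})}
    durations = cfg["duration_ms"]
    ensembles = {}
    for T in cfg["temperatures_c"]:
        ccfg = CouplingConfig(
            temperature_c=T,
            duration=(durations[T] if isinstance(durations, dict) else durations),
            n_replicas=cfg["n_replicas"],
            base_seed=seed,
            clamp=CurrentClampSpec(cfg["clamp_pA"], onset_ms=cfg["clamp_onset_ms"],
                                   duration_ms=cfg["clamp_duration_ms"]),
        )
        ensembles[T] = run_ensemble(ccfg, params=params)
        logger.info("T=%g: median repolarization %.2f ms", T,
                    ensembles[T].median_metric("repolarization_ms"))
    temps = sorted(cfg["temperatures_c"])
    ratio = (repolarization_ratio(ensembles[temps[0]], ensembles[temps[-1]])
             if len(temps) >= 2 else np.nan)
    result = {"ensembles": ensembles, "repolarization_ratio_cold_over_warm": ratio,
              "seed": seed, "config": cfg}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        metrics_all = []
        for T, ens in ensembles.items():
            agg = pd.DataFrame({"t_ms": ens.t, "median_mV": ens.median,
                                "q1_mV": ens.q1, "q3_mV": ens.q3})
            agg.to_csv(outdir / f"aggregate_T{T:g}.csv", index=False)
            m = ens.metrics.copy()
            m.insert(0, "temperature_c", T)
            metrics_all.append(m)
            if cfg["write_traces"]:
                for k in range(ens.traces.shape[0]):
                    pd.DataFrame({"t_ms": ens.t, "vm_mV": ens.traces[k]}).to_csv(
                        outdir / f"trace_T{T:g}_rep{k:03d}.csv", index=False)
        pd.concat(metrics_all).to_csv(outdir / "metrics.csv", index=False)
        _write_manifest(outdir, "coupled_spike", cfg, seed,
                        extra={"repolarization_ratio": ratio})
    return result


# ---------------------------------------------------------------------------
# permeation
# ---------------------------------------------------------------------------

DEFAULT_PERMEATION_CFG = {
    "n_ions": 20,
    "mean_crossings": 3.0,
    "z_lower_A": -15.0,
    "z_upper_A": 15.0,
    "duration_ns": 500.0,
    "vm_mV": 600.0,
    "n_replicates": 5,
    "tracks_csv": None,  # analyse an existing file instead of synthesizing
}


def permeation(config: dict | None = None, seed: int = 0,
               outdir: str | Path | None = None) -> dict:
    """Estimate single-channel conductance from ion tracks."""
    cfg = {**DEFAULT_PERMEATION_CFG, **(config or {})}
    bounds = MembraneBounds(cfg["z_lower_A"], cfg["z_upper_A"])
    rows = []
    if cfg["tracks_csv"]:
        tracks = tracks_from_csv(cfg["tracks_csv"])
        current, g = conductance_from_tracks(tracks, bounds, cfg["duration_ns"],
                                             cfg["vm_mV"])
        rows.append({"replicate": 0, "net_crossings":
                     sum(count_crossings(t, bounds) for t in tracks),
                     "current_pA": current, "conductance_pS": g})
    else:
        seq = np.random.SeedSequence(seed)
        for r, child in enumerate(seq.spawn(cfg["n_replicates"])):
            tracks, truth = generate_synthetic_tracks(
                cfg["n_ions"], cfg["mean_crossings"], bounds,
                rng_seed=np.random.default_rng(child))
            current, g = conductance_from_tracks(tracks, bounds,
                                                 cfg["duration_ns"], cfg["vm_mV"])
            rows.append({"replicate": r, "ground_truth_crossings": truth,
                         "net_crossings": sum(count_crossings(t, bounds)
                                              for t in tracks),
                         "current_pA": current, "conductance_pS": g})
    table = pd.DataFrame(rows)
    out = {"table": table, "seed": seed, "config": cfg}
    if len(table) >= 2:
        mean, sem = replicate_stats(table["conductance_pS"])
        out["g_mean_pS"], out["g_stderr_pS"] = mean, sem
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "conductance.csv", index=False)
        _write_manifest(outdir, "permeation", cfg, seed)
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def fixtures(config: dict | None = None, seed: int = 0,
             outdir: str | Path = "fixtures") -> dict:
    """Write the synthetic input files: variant table, morphologies, ion
    tracks (with ground truth) and example spike trains."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(seed)
    s_tree, s_tracks, s_trains = seq.spawn(3)

    vt = VariantTable.default()
    vt.to_csv(outdir / "variant_table.csv")
    vt.factors().to_csv(outdir / "scaling_factors.csv", index=False)

    bs = generate_synthetic_morphology("ball_and_stick", length=600.0)
    write_swc(bs, outdir / "ball_and_stick.swc")
    tree = generate_synthetic_morphology(
        "random_binary_tree", depth=5, rng_seed=np.random.default_rng(s_tree))
    write_swc(tree, outdir / "binary_tree.swc")

    bounds = MembraneBounds(-15.0, 15.0)
    tracks, truth = generate_synthetic_tracks(
        20, 3.0, bounds, rng_seed=np.random.default_rng(s_tracks))
    tracks_to_csv(tracks, outdir / "ion_tracks.csv")
    (outdir / "ion_tracks_ground_truth.json").write_text(
        json.dumps({"net_crossings": truth, "z_lower_A": -15.0, "z_upper_A": 15.0}))

    trains = make_inputs(10, 10.0, (0.0, 1000.0), correlated=False,
                         rng_seed=s_trains)
    trains_to_csv(trains, outdir / "spike_trains.csv")
    _write_manifest(outdir, "fixtures", config or {}, seed)
    return {"outdir": outdir, "variant_table": vt, "ground_truth_crossings": truth}


def _write_manifest(outdir: Path, workflow: str, cfg: dict, seed: int,
                    extra: dict | None = None) -> None:
    manifest = {"workflow": workflow, "version": __version__, "seed": seed,
                "config": {k: v for k, v in cfg.items()
                           if isinstance(v, (int, float, str, bool, list, dict,
                                             type(None)))}}
    if extra:
        manifest.update(extra)
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                           default=str))
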