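"""End-to-end study replica: preprocess -> spectra -> phase -> modulation -> stats.

``run_study`` executes the full analysis on a cohort of hemisphere sessions
(synthetic generator configs or saved session files): per-channel modulograms
and MI spectra, per-hemisphere maxima, the stepping-variability vs maximum-MI
correlation (exact Spearman), the regular vs less-regular cycle contrast
(exact Wilcoxon), optional condition contrasts of PSD/imaginary coherence,
and optional HMM state clustering.  Everything is reproducible from the
config's seeds; the JSON summary is byte-stable across reruns.

Aggregation follows the channel -> hemisphere -> group order: a hemisphere's
modulogram is the mean over its bipolar channels and the group modulogram
the mean over hemispheres.  Each hemisphere's phase reference is the
contralateral foot; sessions here carry one hemisphere, whose contralateral
foot is by convention the generator's right foot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gaitphase, modulation, permstats, preprocess, spectral, states
from .synthgait import SessionConfig, SyntheticSession, generate_session, load_session

__all__ = ["StudyConfig", "run_study", "analyze_hemisphere"]

DEFAULT_BANDS = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (55.0, 95.0),
}


@dataclass
class StudyConfig:
    """Configuration of one study replica.

    ``sessions`` lists per-hemisphere inputs: :class:`SessionConfig` objects
    (generated on the fly) or paths to saved session HDF5 files.  ``bands``
    are the summary frequency bands; ``mi_band`` the wide band over which the
    maximum MI is taken.  ``selector`` picks each hemisphere's
    "strongest-modulation" channel by ``"max_mi"`` or ``"max_cluster_mass"``.
    """

    sessions: list = field(default_factory=list)
    condition_sessions: list = field(default_factory=list)
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    mi_band: tuple = (1.0, 95.0)
    freq_step: float = 1.0
    tfr_decim: int = 8
    n_perm: int = 200
    alpha: float = 0.05
    selector: str = "max_mi"
    seed: int = 0
    run_cluster_perm: bool = False
    run_states: bool = False
    n_states_max: int = 8
    states_fs: float = 256.0
    out_dir: str | None = None


def _load(entry, default_seed: int) -> SyntheticSession:
    if isinstance(entry, SessionConfig):
        return generate_session(entry)
    if isinstance(entry, (str, Path)):
        return load_session(entry)
    raise TypeError(f"cannot interpret session entry of type {type(entry)!r}")


def analyze_hemisphere(session: SyntheticSession, cfg: StudyConfig,
                       seed: int) -> dict:
    """Single-hemisphere analysis: preprocessing, phase, modulograms, MI."""
    rec = preprocess.preprocess_recording(session.recording)
    lfp_labels = [l for l, k in zip(rec.labels, rec.kinds) if k == "lfp"]
    bip = preprocess.make_bipolar(rec, lfp_labels)

    # contralateral foot: right force trace of this hemisphere's session
    phase, cycles = gaitphase.phase_from_force(rec.get("force_right"), rec.fs)

    freqs = spectral.default_freqs(step=cfg.freq_step)
    tfr = spectral.morlet_tfr(bip, freqs=freqs, decim=cfg.tfr_decim)
    phase_dec = phase.decimate(cfg.tfr_decim)
    phase_dec = gaitphase.PhaseSeries(
        phase_dec.phase[: tfr.n_times], phase_dec.valid[: tfr.n_times],
        phase_dec.fs, phase_dec.strike_anchored)

    per_channel = []
    for i, lab in enumerate(tfr.labels):
        m = modulation.modulogram(tfr, phase_dec, channel=i)
        mi = modulation.modulation_index(m)
        f_max, v_max = modulation.max_mi(mi, band=cfg.mi_band)
        per_channel.append({
            "label": lab, "modulogram": m, "mi": mi,
            "max_mi_freq": f_max, "max_mi": v_max,
        })

    best = max(range(len(per_channel)),
               key=lambda i: per_channel[i]["max_mi"])
    result = {
        "per_channel": per_channel,
        "best_channel": per_channel[best]["label"],
        "best_channel_index": best,
        "max_mi": per_channel[best]["max_mi"],
        "max_mi_freq": per_channel[best]["max_mi_freq"],
        "variability_s": gaitphase.cycle_variability(cycles),
        "n_cycles": cycles.n_cycles,
        "hemisphere_modulogram": np.mean(
            [c["modulogram"].mean_norm for c in per_channel], axis=0),
        "hemisphere_mi": np.mean([c["mi"].mi for c in per_channel], axis=0),
        "freqs": tfr.freqs,
        "tfr": tfr,
        "phase": phase_dec,
        "cycles": cycles,
    }

    if cfg.run_cluster_perm:
        perm = permstats.cluster_perm_modulogram(
            tfr, phase_dec, cycles, n_perm=cfg.n_perm, alpha=cfg.alpha,
            seed=seed, channel=best)
        result["cluster_perm"] = perm
        if cfg.selector == "max_cluster_mass":
            masses = []
            for i in range(len(per_channel)):
                pr = permstats.cluster_perm_modulogram(
                    tfr, phase_dec, cycles, n_perm=cfg.n_perm,
                    alpha=cfg.alpha, seed=seed + 7 * i, channel=i)
                masses.append(max((c.mass for c in pr.clusters), default=0.0))
            best = int(np.argmax(masses))
            result["best_channel"] = per_channel[best]["label"]
            result["best_channel_index"] = best

    # regular / less-regular cycle split (needs >= 8 cycles)
    if cycles.n_cycles >= 8:
        split = gaitphase.split_regularity(cycles)
        result["regularity"] = {}
        for name, idx in (("regular", split.regular_idx),
                          ("less_regular", split.less_regular_idx)):
            sub_valid = np.zeros_like(phase.valid)
            for j in idx:
                lo = int(cycles.lift_sample[j])
                hi = int(cycles.next_lift_sample[j])
                sub_valid[lo:hi] = True
            sub = gaitphase.PhaseSeries(
                phase.phase, phase.valid & sub_valid, phase.fs,
                phase.strike_anchored)
            m = modulation.modulogram(tfr, sub, channel=best)
            mi = modulation.modulation_index(m)
            _, v = modulation.max_mi(mi, band=cfg.mi_band)
            result["regularity"][name] = v
        result["regularity"]["mean_deviation"] = {
            "regular": float(np.mean(split.deviation_s[split.regular_idx])),
            "less_regular": float(
                np.mean(split.deviation_s[split.less_regular_idx])),
        }

    if cfg.run_states:
        lfp_ds = preprocess.resample(bip, cfg.states_fs)
        factor = int(round(rec.fs / cfg.states_fs))
        sm = states.fit_state_model(
            lfp_ds, n_states_max=cfg.n_states_max, seed=seed)
        ph_states = phase.decimate(factor)
        n = min(len(sm.state_sequence), len(ph_states.phase))
        ph_states = gaitphase.PhaseSeries(
            ph_states.phase[:n], ph_states.valid[:n], ph_states.fs,
            ph_states.strike_anchored)
        hists = states.occupancy_histograms(
            states.StateModel(sm.model, sm.state_sequence[:n],
                              sm.fractional_occupancy, sm.kept_states,
                              sm.log_likelihoods, sm.fs, sm.ar_order),
            ph_states)
        result["states"] = {
            "model": sm,
            "histograms": hists,
            "clustering": (states.cluster_histograms(hists, k=3, seed=seed)
                           if len(hists) >= 3 else None),
        }
    return result


def _psd_for_condition(session: SyntheticSession, cfg: StudyConfig
                       ) -> np.ndarray:
    rec = preprocess.preprocess_recording(session.recording)
    lfp_labels = [l for l, k in zip(rec.labels, rec.kinds) if k == "lfp"]
    bip = preprocess.make_bipolar(rec, lfp_labels)
    freqs = spectral.default_freqs(step=cfg.freq_step)
    tfr = spectral.morlet_tfr(bip, freqs=freqs, decim=cfg.tfr_decim)
    psd = spectral.psd_percent(tfr)
    return psd.values.mean(axis=0)  # hemisphere average over channels


def run_study(cfg: StudyConfig) -> dict:
    """Run the full study replica; returns the report bundle.

    The returned dict carries a JSON-serializable ``summary`` plus the
    in-memory per-hemisphere artifacts under ``hemispheres``.  With
    ``cfg.out_dir`` set, ``summary`` is written to ``summary.json`` there.
    """
    if not cfg.sessions:
        raise ValueError("study config lists no sessions")
    hemis = []
    errors = []
    for i, entry in enumerate(cfg.sessions):
        try:
            session = _load(entry, cfg.seed + i)
            hemis.append(analyze_hemisphere(session, cfg, seed=cfg.seed + 1000 + i))
        except Exception as exc:  # keep partial outputs, report stage
            errors.append({"session": i, "stage": "hemisphere", "error": str(exc)})
    if not hemis:
        raise RuntimeError(f"all sessions failed: {errors}")

    max_mis = np.array([h["max_mi"] for h in hemis])
    variab = np.array([h["variability_s"] for h in hemis])
    summary = {
        "n_hemispheres": len(hemis),
        "max_mi": [round(float(v), 10) for v in max_mis],
        "max_mi_freq": [float(h["max_mi_freq"]) for h in hemis],
        "variability_s": [round(float(v), 10) for v in variab],
        "best_channel": [h["best_channel"] for h in hemis],
        "errors": errors,
    }

    if 3 <= len(hemis) <= 9:
        rho, p = permstats.spearman_exact(variab, max_mis)
        summary["variability_mi_spearman"] = {"rho": round(rho, 10),
                                              "p": round(p, 10)}
    reg = [h["regularity"]["regular"] for h in hemis if "regularity" in h]
    irr = [h["regularity"]["less_regular"] for h in hemis if "regularity" in h]
    if 2 <= len(reg) <= 25 and len(reg) == len(irr):
        try:
            W, p = permstats.wilcoxon_exact(reg, irr)
            summary["regular_vs_less_regular_wilcoxon"] = {
                "W": W, "p": round(p, 10),
                "mean_regular_mi": round(float(np.mean(reg)), 10),
                "mean_less_regular_mi": round(float(np.mean(irr)), 10),
            }
        except ValueError as exc:
            errors.append({"stage": "wilcoxon", "error": str(exc)})

    group_modulogram = np.mean([h["hemisphere_modulogram"] for h in hemis],
                               axis=0)
    group_mi = np.mean([h["hemisphere_mi"] for h in hemis], axis=0)
    freqs = hemis[0]["freqs"]
    for band, (lo, hi) in cfg.bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        summary.setdefault("band_mean_mi", {})[band] = round(
            float(group_mi[sel].mean()), 10)

    if cfg.condition_sessions:
        if len(cfg.condition_sessions) != len(cfg.sessions):
            errors.append({"stage": "conditions",
                           "error": "condition session count mismatch"})
        else:
            psd_a = np.vstack([
                _psd_for_condition(_load(e, cfg.seed + i), cfg)
                for i, e in enumerate(cfg.sessions)])
            psd_b = np.vstack([
                _psd_for_condition(_load(e, cfg.seed + i), cfg)
                for i, e in enumerate(cfg.condition_sessions)])
            pr = permstats.cluster_perm_conditions(
                psd_a, psd_b, n_perm=cfg.n_perm, seed=cfg.seed, freqs=freqs)
            summary["condition_contrast"] = {
                "n_clusters": len(pr.clusters),
                "cluster_p": [round(c.p_value, 10) for c in pr.clusters],
            }

    report = {
        "summary": summary,
        "hemispheres": hemis,
        "group_modulogram": group_modulogram,
        "group_mi": group_mi,
        "freqs": freqs,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        np.savetxt(out / "group_modulogram.csv", group_modulogram,
                   delimiter=",")
        np.savetxt(out / "group_mi.csv",
                   np.column_stack([freqs, group_mi]), delimiter=",",
                   header="freq_hz,mi", comments="")
    return report
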