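"""Configuration and the end-to-end cohort simulation / analysis pipeline.

``run_all`` simulates a cohort subject by subject: learning-phase streams are
rendered and pooled across conditions for the frequency-tagging statistics;
test-phase trials are rendered, low-pass filtered, epoched at the second
dependency element and fed per condition into the cluster-permutation test.
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

from . import __version__, agdesign, erp, fileio, spectral, synth
from .agdesign import TimingSpec
from .synth import NadEffect, Recording, SynthParams

__all__ = ["PipelineConfig", "run_all", "reduced_config"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, with full-study-scale defaults."""

    timing: TimingSpec = field(default_factory=TimingSpec)
    synth: SynthParams = field(default_factory=SynthParams)
    n_subjects: int = 31
    n_audios_per_condition: int = 4
    chunks_per_audio: int = 144
    epoch_chunks: int = 8
    fmin: float = 0.1
    fmax: float = 10.0
    halfwidth: float = 0.5
    epn_mode: str = "sum"
    n_per_cell: int = 36
    n_target_chunks_per_trial: int = 4
    n_perm: int = 10000
    alpha: float = 0.05
    erp_lowpass_hz: float = 25.0
    erp_tmin: float = -0.1
    erp_tmax: float = 0.3
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        d["synth"]["nad_effect"] = {
            cond: dataclasses.asdict(eff) for cond, eff in self.synth.nad_effect.items()
        }
        if self.synth.topography is not None:
            d["synth"]["topography"] = list(map(float, self.synth.topography))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        timing = TimingSpec(**d.pop("timing", {}))
        synth_d = dict(d.pop("synth", {}))
        if "nad_effect" in synth_d:
            synth_d["nad_effect"] = {
                cond: NadEffect(**eff) for cond, eff in synth_d["nad_effect"].items()
            }
        if synth_d.get("topography") is not None:
            synth_d["topography"] = np.asarray(synth_d["topography"], dtype=float)
        return cls(timing=timing, synth=SynthParams(**synth_d), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]


def reduced_config(**overrides) -> PipelineConfig:
    """A small preset (5 subjects, 1 audio/condition, 500 permutations)."""
    defaults = dict(
        n_subjects=5,
        n_audios_per_condition=1,
        chunks_per_audio=48,
        n_per_cell=8,
        n_perm=500,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def _learning_pairs(inventory: agdesign.SyllableInventory):
    return inventory.dependency_pairs[0], inventory.dependency_pairs[1]


def simulate_subject_learning(
    cfg: PipelineConfig, subject_seed: np.random.SeedSequence
) -> erp.EpochSet:
    """Render one subject's learning-phase audios and pool all epochs."""
    inventory = agdesign.default_inventory()
    within_pair, across_pair = _learning_pairs(inventory)
    children = iter(subject_seed.spawn(2 * cfg.n_audios_per_condition * 2))
    epoch_blocks = []
    for condition in ("within", "across"):
        for _ in range(cfg.n_audios_per_condition):
            design_seed, noise_seed = next(children), next(children)
            if condition == "within":
                events = agdesign.make_within_stream(
                    within_pair, cfg.chunks_per_audio // 2, inventory, cfg.timing,
                    seed=design_seed,
                )
            else:
                events = agdesign.make_across_stream(
                    across_pair, cfg.chunks_per_audio, inventory, cfg.timing,
                    seed=design_seed,
                )
            rec = synth.render_recording(events, cfg.synth, seed=noise_seed)
            epochs = spectral.epochs_from_stream(
                rec, cfg.timing, n_chunks=cfg.epoch_chunks
            )
            epoch_blocks.append(epochs.data)
    data = np.concatenate(epoch_blocks, axis=0)
    first = epoch_blocks[0]
    return erp.EpochSet(
        data=data,
        srate=cfg.synth.srate,
        tmin=0.0,
        tmax=(first.shape[2] - 1) / cfg.synth.srate,
    )


def learning_group_stats(cfg: PipelineConfig, subject_seeds) -> dict:
    """Per-subject channel-averaged EPn/ITPC at target and neighbour bins,
    plus group target-vs-neighbour paired t tests."""
    per_subject: dict[str, list] = {
        "epn_chunk": [], "epn_syllable": [], "itpc_chunk": [], "itpc_syllable": [],
        "epn_chunk_nb": [], "epn_syllable_nb": [], "itpc_chunk_nb": [], "itpc_syllable_nb": [],
    }
    group_spectra = []
    for sseed in subject_seeds:
        epochs = simulate_subject_learning(cfg, sseed)
        spec = spectral.compute_spectrum(
            epochs, cfg.timing, fmin=cfg.fmin, fmax=cfg.fmax,
            halfwidth=cfg.halfwidth, mode=cfg.epn_mode,
        )
        for measure in ("epn", "itpc"):
            values = spec.channel_average(measure)
            for rate in ("chunk", "syllable"):
                bin_ = spec.target_bins[rate]
                nb = spectral.neighbor_bins(spec.freqs, spec.freqs[bin_])
                per_subject[f"{measure}_{rate}"].append(values[bin_])
                per_subject[f"{measure}_{rate}_nb"].append(values[nb])
        group_spectra.append(
            np.column_stack(
                [spec.channel_average("epn"), spec.channel_average("itpc")]
            )
        )
        freqs = spec.freqs
    stats: dict = {"freqs": freqs, "mean_spectrum": np.mean(group_spectra, axis=0)}
    for measure in ("epn", "itpc"):
        for rate in ("chunk", "syllable"):
            target = np.asarray(per_subject[f"{measure}_{rate}"])
            nb = np.asarray(per_subject[f"{measure}_{rate}_nb"])
            t, p = spectral.target_vs_neighbors(target, nb)
            stats[f"{measure}_{rate}"] = {
                "target_mean": float(target.mean()),
                "neighbor_mean": float(nb.mean()),
                "t": t,
                "p": p,
            }
    return stats


def simulate_subject_test(
    cfg: PipelineConfig, subject_seed: np.random.SeedSequence
) -> dict[tuple[str, str], np.ndarray]:
    """Per-subject mean ERP epochs keyed by (condition, match/violation)."""
    inventory = agdesign.default_inventory()
    pairs = _learning_pairs(inventory)
    trial_seed, noise_master = subject_seed.spawn(2)
    trials = agdesign.make_test_trials(
        pairs, inventory, cfg.timing, seed=trial_seed,
        n_per_cell=cfg.n_per_cell,
        n_target_chunks=cfg.n_target_chunks_per_trial,
    )
    noise_seeds = noise_master.spawn(len(trials))
    sums: dict[tuple[str, str], np.ndarray] = {}
    counts: dict[tuple[str, str], int] = {}
    for events, nseed in zip(trials, noise_seeds):
        rec = synth.render_recording(events, cfg.synth, seed=nseed)
        filtered = Recording(
            data=erp.lowpass(rec.data, cfg.erp_lowpass_hz, srate=rec.srate),
            srate=rec.srate,
            channel_labels=rec.channel_labels,
            adjacency=rec.adjacency,
        )
        epochs = erp.epoch_and_baseline(
            filtered, events, tmin=cfg.erp_tmin, tmax=cfg.erp_tmax
        )
        condition = events["condition"].iloc[0]
        for i in range(epochs.n_trials):
            role = epochs.labels["role"].iloc[i]
            key = (condition, "match" if role == "dep_second" else "violation")
            if key not in sums:
                sums[key] = np.zeros_like(epochs.data[i])
                counts[key] = 0
            sums[key] += epochs.data[i]
            counts[key] += 1
    return {key: sums[key] / counts[key] for key in sums}


def erp_group_stats(cfg: PipelineConfig, subject_seeds, perm_seed) -> dict:
    """Cluster-permutation test of match vs violation per condition."""
    means: dict[tuple[str, str], list[np.ndarray]] = {}
    for sseed in subject_seeds:
        subject_means = simulate_subject_test(cfg, sseed)
        for key, value in subject_means.items():
            means.setdefault(key, []).append(value)
    _, adjacency = synth.grid_adjacency(cfg.synth.n_channels)
    out: dict = {}
    perm_children = np.random.SeedSequence(perm_seed).spawn(2) if not isinstance(
        perm_seed, np.random.SeedSequence
    ) else perm_seed.spawn(2)
    for condition, pseed in zip(("within", "across"), perm_children):
        cond_a = np.stack(means[(condition, "match")])
        cond_b = np.stack(means[(condition, "violation")])
        result = erp.cluster_permutation(
            cond_a, cond_b, adjacency,
            alpha_cluster=cfg.alpha, n_perm=cfg.n_perm, seed=pseed,
        )
        out[condition] = {
            "n_clusters": len(result.clusters),
            "min_cluster_p": result.min_p,
            "significant": bool(result.min_p < cfg.alpha),
            "result": result,
        }
    return out


def run_all(cfg: PipelineConfig, outdir=None) -> dict:
    """Simulate a cohort and run both analysis stages; optionally write outputs.

    Returns a JSON-serializable summary; when ``outdir`` is given, writes
    ``summary.json``, ``report.txt`` and the group-mean spectrum table there.
    """
    master = np.random.SeedSequence(cfg.seed)
    learn_seeds_master, test_seeds_master, perm_seed = master.spawn(3)
    learn_seeds = learn_seeds_master.spawn(cfg.n_subjects)
    test_seeds = test_seeds_master.spawn(cfg.n_subjects)

    learning = learning_group_stats(cfg, learn_seeds)
    erp_stats = erp_group_stats(cfg, test_seeds, perm_seed)

    summary = {
        "tool": f"chunktag {__version__}",
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_subjects": cfg.n_subjects,
        "learning": {
            key: learning[key]
            for key in ("epn_chunk", "epn_syllable", "itpc_chunk", "itpc_syllable")
        },
        "erp": {
            cond: {
                "n_clusters": stats["n_clusters"],
                "min_cluster_p": stats["min_cluster_p"],
                "significant": stats["significant"],
            }
            for cond, stats in erp_stats.items()
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        spectrum = pd.DataFrame(
            {
                "frequency": learning["freqs"],
                "epn": learning["mean_spectrum"][:, 0],
                "itpc": learning["mean_spectrum"][:, 1],
            }
        )
        fileio.write_table(
            spectrum, outdir / "group_spectrum.tsv",
            seed=cfg.seed, config_hash=cfg.config_hash(),
        )
        for cond, stats in erp_stats.items():
            fileio.write_table(
                stats["result"].cluster_table(), outdir / f"clusters_{cond}.tsv",
                seed=cfg.seed, config_hash=cfg.config_hash(),
            )
        (outdir / "report.txt").write_text(_format_report(summary), encoding="utf-8")
    return summary


def _format_report(summary: dict) -> str:
    lines = [
        f"{summary['tool']} cohort report",
        f"seed={summary['seed']} config={summary['config_hash']} "
        f"subjects={summary['n_subjects']}",
        "",
        "Learning phase (target vs neighbouring bins, paired t):",
    ]
    for key in ("epn_chunk", "epn_syllable", "itpc_chunk", "itpc_syllable"):
        s = summary["learning"][key]
        lines.append(
            f"  {key:14s} target={s['target_mean']:.4f} "
            f"neighbors={s['neighbor_mean']:.4f} t={s['t']:.2f} p={s['p']:.2e}"
        )
    lines.append("")
    lines.append("Test phase (match vs violation, cluster permutation):")
    for cond, s in summary["erp"].items():
        flag = "SIGNIFICANT" if s["significant"] else "n.s."
        lines.append(
            f"  {cond:7s} clusters={s['n_clusters']} "
            f"min_p={s['min_cluster_p']:.4f} {flag}"
        )
    return "\n".join(lines) + "\n"
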