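"""Configuration-driven orchestration of the full analysis chain.

``run_pipeline`` executes simulate -> balance -> insulation -> domains ->
loops -> compartments -> aggregate for each configured sample and writes a
manifest (parameter echo, per-stage statistics, content hashes of every
output file). Everything downstream of the seed is deterministic, so the
same configuration and seed reproduce identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import balance as bal
from . import compartments as comp
from . import domains as dom
from . import insulation as ins
from . import io as hio
from . import loops as lps
from . import synth

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's printed values
    (2-kb bins, 50-kb insulation window, span 10, threshold -0.25, arrowhead
    cutoffs 0.95/6/1.05, loop range 4-100 kb, q < 0.05, balancing eps 1e-4).
    """

    out_dir: str = "tadshift_out"
    seed: int = 0
    # simulation (used when simulate=True); samples map name -> preset
    simulate: bool = True
    samples: dict[str, str] = field(
        default_factory=lambda: {"wt": "wt", "mutant": "mutant"}
    )
    # 2 Mb at 2 kb: long enough for every stage (compartment runs included)
    n_bins: int = 1000
    bin_size: int = 2000
    depth: float = 2e6
    bias_sigma: float = 0.2
    with_loops: bool = True
    with_compartments: bool = True
    # pre-binned inputs (used when simulate=False): name -> [bins, triplets]
    maps: dict[str, list[str]] = field(default_factory=dict)
    # balancing
    eps: float = 1e-4
    max_iter: int = 200
    min_marginal_quantile: float = 0.02
    # insulation
    window_bp: int = 50_000
    span: int = 10
    threshold: float = -0.25
    exclude_path: str | None = None
    # domains
    pixel_cutoff: float = 0.95
    min_pixels: int = 6
    border_min: float = 1.05
    min_domain_bp: int = 12_000
    max_domain_bp: int = 500_000
    oe_max_dist_bp: int = 500_000
    # loops
    d_min: int = 4000
    d_max: int = 100_000
    q_max: float = 0.05
    n_occupancy_bins: int = 40
    # compartments
    coarse_bin_bp: int = 50_000
    min_gap_ratio: float = 3.0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.min_marginal_quantile < 1, "min_marginal_quantile"),
            (self.eps > 0, "eps"),
            (self.window_bp >= self.bin_size, "window_bp"),
            (self.span >= 3, "span"),
            (self.min_pixels >= 1, "min_pixels"),
            (0 < self.q_max < 1, "q_max"),
            (self.d_min < self.d_max, "d_min/d_max"),
            (self.min_domain_bp < self.max_domain_bp, "min/max_domain_bp"),
            (self.depth >= 0, "depth"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"invalid configuration value for {name}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every sample and return the manifest dict.

    On a stage failure a ``<sample>.<stage>.partial`` marker is left in the
    output directory and :class:`StageError` names the failing stage.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "samples": {},
        "comparison": {},
    }
    per_sample: dict[str, dict] = {}

    names = list(config.samples) if config.simulate else list(config.maps)
    for k, name in enumerate(names):
        state: dict = {}
        stats: dict = {}
        files: dict[str, str] = {}
        out = os.path.join(config.out_dir, name)
        os.makedirs(out, exist_ok=True)

        def stage(label, fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - report stage and cause
                open(os.path.join(config.out_dir, f"{name}.{label}.partial"), "w").close()
                raise StageError(label, e) from e

        def run_simulate():
            cfg = synth.demo_config(
                config.samples[name],
                n_bins=config.n_bins,
                bin_size=config.bin_size,
                depth=config.depth,
                seed=config.seed + k,
                bias_sigma=config.bias_sigma,
                with_loops=config.with_loops,
                with_compartments=config.with_compartments,
            )
            cmap, truth = synth.simulate(cfg)
            files.update(
                {f"truth_{lbl}": p for lbl, p in synth.write_truth(
                    truth, os.path.join(out, "truth")).items()}
            )
            files.update(
                {f"raw_{lbl}": p for lbl, p in hio.write_contact_map(
                    cmap, os.path.join(out, "raw")).items()}
            )
            return cmap, truth

        if config.simulate:
            cmap, truth = stage("simulate", run_simulate)
            state["truth"] = truth
        else:
            cmap = stage(
                "load", lambda: hio.load_contact_map(*config.maps[name])
            )
            state["truth"] = None

        def run_balance():
            mask = bal.select_valid_bins(cmap, config.min_marginal_quantile)
            masked = cmap.with_mask(mask)
            balanced, result = bal.ice_balance(masked, config.eps, config.max_iter)
            stats["balance"] = {
                "n_bins_masked": int((~mask).sum()),
                "n_iterations": result.n_iterations,
                "final_eps": result.final_eps,
            }
            files.update(
                {f"balanced_{lbl}": p for lbl, p in hio.write_contact_map(
                    balanced, os.path.join(out, "balanced")).items()}
            )
            return balanced

        balanced = stage("balance", run_balance)

        exclude = None
        if config.exclude_path:
            exclude = hio.read_intervals(config.exclude_path, "bed")

        def run_insulation():
            track = ins.insulation_track(balanced, config.window_bp, exclude)
            minima = ins.local_minima(track, config.span)
            regions = ins.insulated_regions(track, minima, config.threshold)
            bdf = balanced.bins.df
            tdf = pd.DataFrame(
                {
                    "chrom": bdf["chrom"],
                    "start": bdf["start"],
                    "end": bdf["end"],
                    "value": np.where(track.valid, track.score, np.nan),
                }
            )
            files["insulation_bedgraph"] = hio.write_bedgraph(
                tdf[track.valid], os.path.join(out, "insulation.bedgraph")
            )
            files["insulated_regions"] = _write_tsv(
                ins.regions_to_frame(regions),
                os.path.join(out, "insulated_regions.tsv"),
            )
            stats["insulation"] = {
                "n_valid_bins": int(track.valid.sum()),
                "n_minima": int(len(minima)),
                "n_insulated_regions": len(regions),
            }
            return track, minima, regions

        track, minima, regions = stage("insulation", run_insulation)

        def run_domains():
            oe = dom.observed_over_expected(balanced, config.oe_max_dist_bp)
            ends = {s.start for _, _, s in balanced.bins.arm_slices()} | {
                s.stop for _, _, s in balanced.bins.arm_slices()
            }
            boundaries = sorted(
                {r.start_bin for r in regions}
                | {r.end_bin for r in regions}
                | ends
            )
            cands = dom.candidate_domains(
                np.array(boundaries, dtype=int),
                balanced.bins,
                config.min_domain_bp,
                config.max_domain_bp,
            )
            cands = dom.refine_candidates(oe, cands, config.border_min)
            calls = dom.call_domains(
                oe,
                cands,
                config.pixel_cutoff,
                config.min_pixels,
                config.border_min,
                exclude,
            )
            files["domains"] = _write_tsv(
                dom.calls_to_frame(calls), os.path.join(out, "domains.tsv")
            )
            stats["domains"] = {"n_candidates": len(cands), "n_calls": len(calls)}
            return oe, calls

        oe, calls = stage("domains", run_domains)

        def run_loops():
            model = lps.distance_expected_model(
                cmap.with_mask(balanced.mask),
                balanced.biases,
                config.d_min,
                config.d_max,
                config.n_occupancy_bins,
            )
            table = lps.loop_significance(
                cmap.with_mask(balanced.mask), model, balanced.biases
            )
            called = lps.call_loops(table, config.q_max)
            files["loops"] = _write_tsv(called, os.path.join(out, "loops.tsv"))
            stats["loops"] = {
                "n_pairs_tested": len(table),
                "n_calls": len(called),
                "total_contacts_modeled": int(table["observed"].sum()),
            }
            return table, called

        table, called = stage("loops", run_loops)

        def run_compartments():
            truth = state["truth"]
            reference = None
            if truth is not None and (truth.labels != "").any():
                bdf = balanced.bins.df
                reference = pd.DataFrame(
                    {
                        "chrom": bdf["chrom"],
                        "start": bdf["start"],
                        "end": bdf["end"],
                        "value": (truth.labels == "A").astype(float),
                    }
                )
            ctrack = comp.compartment_eigenvector(
                balanced,
                config.coarse_bin_bp,
                reference,
                config.min_gap_ratio,
            )
            cdf = ctrack.bins.df.assign(value=ctrack.value, label=ctrack.label)
            files["compartments"] = _write_tsv(
                cdf, os.path.join(out, "compartments.tsv")
            )
            stats["compartments"] = {
                "n_labeled": int((ctrack.label != "").sum()),
            }
            return ctrack

        ctrack = stage("compartments", run_compartments)

        def run_aggregate():
            curve = agg.decay_curve(balanced)
            files["decay_curve"] = _write_tsv(
                curve, os.path.join(out, "decay_curve.tsv")
            )
            if calls:
                pileup = agg.rescaled_domain_pileup(
                    oe, [(c.start_bin, c.end_bin) for c in calls]
                )
                pdf = pd.DataFrame(pileup.matrix)
                files["domain_pileup"] = _write_tsv(
                    pdf, os.path.join(out, "domain_pileup.tsv")
                )
                stats["aggregate"] = {"pileup_n_domains": pileup.n_loci}
            return curve

        stage("aggregate", run_aggregate)

        per_sample[name] = {
            "track": track,
            "calls": calls,
            "loops": called,
            "ctrack": ctrack,
        }
        manifest["samples"][name] = {
            "stats": stats,
            "files": {
                lbl: {"path": os.path.relpath(p, config.out_dir), "sha256": _sha256(p)}
                for lbl, p in sorted(files.items())
            },
        }

    if len(names) >= 2:
        a, b = names[0], names[1]
        sa, sb = per_sample[a], per_sample[b]
        cmp_stats: dict = {
            "n_domains": {n: len(per_sample[n]["calls"]) for n in names},
        }
        r = agg.track_correlation([sa["track"], sb["track"]])[0, 1]
        cmp_stats["insulation_pearson_r"] = None if np.isnan(r) else float(r)
        if len(sa["loops"]) and len(sb["loops"]):
            _, fracs = lps.compare_loop_sets(sa["loops"], sb["loops"])
            cmp_stats["shared_loop_fraction"] = {
                cls: (None if np.isnan(v) else v) for cls, v in fracs.items()
            }
        try:
            cmp_stats["compartment_swap_fraction"] = comp.compartment_swap_fraction(
                sa["ctrack"], sb["ctrack"]
            )
        except ValueError:
            cmp_stats["compartment_swap_fraction"] = None
        manifest["comparison"] = cmp_stats

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
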