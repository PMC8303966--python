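"""Result surfaces: numerosity histograms, scalar variability, the
embedding-space view, and end-to-end experiment orchestration.

A generation experiment produces, per conditioning seed, 64 sampled frames
whose numerosities are estimated by a counter.  This module turns those
estimates into relative-frequency histograms (one per seed), a 2-D
target-by-estimate histogram, per-target mean/SD/exact-match summaries and
the scalar-variability diagnostic (does the spread of estimates grow with
the target?).  The learned seed matrix is examined through centered PCA —
the one-dimensional "number line" hypothesis is operationalised as the
monotonicity of the first principal component's scores in numerosity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._pca import fit_pca
from .generation import SampleBatch, SoSVector
from .model import ParameterTables

__all__ = ["GenerationReport", "EmbeddingMap", "histogram_report",
           "scalar_variability_summary", "pca_view", "run_experiment",
           "HISTOGRAM_BINS", "EXPERIMENT_PRESETS"]

#: support of the estimate histograms: the counter label range plus slack;
#: out-of-range estimates are clipped into the edge bins (and counted).
HISTOGRAM_BINS = np.arange(0, 13)


@dataclass
class GenerationReport:
    """Per-seed counting statistics for a generation experiment."""

    targets: List[Optional[int]]            # intended numerosity per seed
    provenances: List[Tuple]                # seed provenance tags
    estimates: List[np.ndarray]             # raw per-image counts per seed
    rel_freq: np.ndarray                    # (n_seeds, n_bins), rows sum to 1
    hist2d: np.ndarray                      # (n_seeds, n_bins) raw tallies
    summary: pd.DataFrame                   # target, mean, sd, exact_match
    clipped: int = 0                        # estimates forced into edge bins
    bins: np.ndarray = field(
        default_factory=lambda: HISTOGRAM_BINS.copy())

    def to_dict(self) -> Dict:
        return {
            "bins": self.bins.tolist(),
            "targets": [None if t is None else int(t) for t in self.targets],
            "provenances": [list(p) for p in self.provenances],
            "estimates": [e.tolist() for e in self.estimates],
            "rel_freq": self.rel_freq.tolist(),
            "hist2d": self.hist2d.tolist(),
            "summary": self.summary.to_dict(orient="records"),
            "clipped": int(self.clipped),
        }


@dataclass
class EmbeddingMap:
    """PCA view of the seed matrix, rows ordered by ascending numerosity."""

    numerosities: Tuple[int, ...]
    scores: np.ndarray                      # (|N|, k)
    explained_variance_ratio: np.ndarray
    pc1_monotone: bool                      # the "number line" diagnostic
    sign_convention: str = "largest-loading-positive"

    def to_dict(self) -> Dict:
        return {
            "numerosities": list(self.numerosities),
            "scores": self.scores.tolist(),
            "explained_variance_ratio":
                self.explained_variance_ratio.tolist(),
            "pc1_monotone": bool(self.pc1_monotone),
            "sign_convention": self.sign_convention,
        }


def _target_of(sos: SoSVector) -> Optional[int]:
    tag = sos.provenance
    if tag and tag[0] in ("trained", "interpolated"):
        return int(tag[1])
    if tag and tag[0] == "pca_reduced":
        return int(tag[2])
    return None  # extrapolated / external seeds have no ground-truth target


def histogram_report(batches: Sequence[SampleBatch],
                     counts: Sequence[np.ndarray],
                     targets: Optional[Sequence[Optional[int]]] = None
                     ) -> GenerationReport:
    """Tally estimated numerosities per seed.

    ``counts[i]`` must hold one estimate per image of ``batches[i]``.
    Targets default to the numerosity recorded in each seed's provenance
    (None for seeds without one, e.g. extrapolation — their exact-match rate
    is reported as NaN).
    """
    if len(batches) != len(counts):
        raise ValueError("one estimate array per batch required")
    for b, c in zip(batches, counts):
        if len(b.images) != len(np.asarray(c)):
            raise ValueError("estimates misaligned with batch size")
    if targets is None:
        targets = [_target_of(b.sos) for b in batches]
    elif len(targets) != len(batches):
        raise ValueError("one target per batch required")

    lo, hi = HISTOGRAM_BINS[0], HISTOGRAM_BINS[-1]
    rel, hist2d, rows, est_list = [], [], [], []
    clipped = 0
    for batch, est, tgt in zip(batches, counts, targets):
        est = np.asarray(est, dtype=np.int64)
        est_list.append(est)
        clipped += int(np.sum((est < lo) | (est > hi)))
        binned = np.clip(est, lo, hi)
        tally = np.bincount(binned - lo, minlength=len(HISTOGRAM_BINS))
        hist2d.append(tally)
        rel.append(tally / tally.sum())
        rows.append({
            "target": np.nan if tgt is None else int(tgt),
            "provenance": "/".join(str(t) for t in batch.sos.provenance),
            "n_samples": len(est),
            "mean": float(est.mean()),
            "sd": float(est.std(ddof=0)),
            "exact_match": np.nan if tgt is None
            else float(np.mean(est == tgt)),
        })
    return GenerationReport(
        targets=list(targets),
        provenances=[b.sos.provenance for b in batches],
        estimates=est_list,
        rel_freq=np.asarray(rel, dtype=np.float64),
        hist2d=np.asarray(hist2d, dtype=np.int64),
        summary=pd.DataFrame(rows), clipped=clipped)


def scalar_variability_summary(report: GenerationReport
                               ) -> Tuple[pd.DataFrame, Dict]:
    """Per-target mean/SD table plus the Spearman correlation between the
    target numerosity and the SD of its estimates.

    The increase of spread with numerosity is an empirical pattern, not a
    mathematical certainty, so the correlation is reported rather than
    asserted.  With fewer than two distinct targets, or with zero variance
    in the SDs, the correlation is undefined and reported as such.
    """
    table = report.summary.dropna(subset=["target"])[
        ["target", "mean", "sd"]].reset_index(drop=True)
    corr: Dict[str, Union[float, str, None]]
    if table["target"].nunique() < 2:
        corr = {"spearman_rho": None, "p_value": None,
                "error": "correlation needs at least two distinct targets"}
    else:
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # a constant SD column is a defined outcome, reported below
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho, p = stats.spearmanr(table["target"], table["sd"])
        if np.isnan(rho):
            corr = {"spearman_rho": None, "p_value": None,
                    "error": "undefined: estimate SDs are constant"}
        else:
            corr = {"spearman_rho": float(rho), "p_value": float(p)}
    return table, corr


def pca_view(tables: Union[ParameterTables, np.ndarray],
             numerosities: Optional[Sequence[int]] = None) -> EmbeddingMap:
    """Centered PCA of the seed matrix rows (ascending numerosity order).

    ``pc1_monotone`` records whether the first component's scores are
    strictly monotone in numerosity — the operational "number line" check.
    It is expected to hold for a trained model and to fail with high
    probability for randomly initialised seeds.
    """
    if isinstance(tables, ParameterTables):
        W = tables.Ws
        nums = tables.numerosities
    else:
        W = np.asarray(tables)
        nums = tuple(numerosities) if numerosities is not None \
            else tuple(range(1, len(W) + 1))
    if len(W) < 2:
        raise ValueError("PCA view needs at least two seed rows")
    basis = fit_pca(W)
    pc1 = basis.scores[:, 0]
    diffs = np.diff(pc1)
    monotone = bool(np.all(diffs > 0) or np.all(diffs < 0))
    return EmbeddingMap(numerosities=nums, scores=basis.scores,
                        explained_variance_ratio=
                        basis.explained_variance_ratio,
                        pc1_monotone=monotone)


# ---------------------------------------------------------------------------
# experiment orchestration


EXPERIMENT_PRESETS: Dict[str, Dict] = {
    # desk-scale end-to-end run: binary 12x12 uniform dots, tiny model
    "tiny": {
        "family": "uniform", "numerosities": [1, 2, 3], "holdout": [],
        "split_sizes": [1500, 300, 300], "frame": "tiny", "model": "tiny",
        "counter": "area", "probes": [{"mode": "trained", "n": 1},
                                      {"mode": "trained", "n": 2},
                                      {"mode": "trained", "n": 3}],
        "count": 64, "epochs": 40,
    },
    # interpolation probe at desk scale: n=2 held out, seeded by midpoint
    "tiny-interp": {
        "family": "uniform", "numerosities": [1, 2, 3], "holdout": [2],
        "split_sizes": [1500, 300, 300], "frame": "tiny", "model": "tiny",
        "counter": "area", "probes": [{"mode": "trained", "n": 1},
                                      {"mode": "interp", "n": 2},
                                      {"mode": "trained", "n": 3}],
        "count": 64, "epochs": 40,
    },
    # the four full-scale generative conditions plus the shape controls
    "uniform-full": {
        "family": "uniform", "numerosities": list(range(1, 9)),
        "holdout": [], "split_sizes": [16000, 3200, 3200],
        "frame": "paper", "model": "paper", "counter": "area",
        "probes": [{"mode": "trained", "n": n} for n in range(1, 9)],
        "count": 64, "epochs": 50,
    },
    "nonuniform-full": {
        "family": "nonuniform", "numerosities": list(range(1, 9)),
        "holdout": [], "split_sizes": [16000, 3200, 3200],
        "frame": "paper", "model": "paper", "counter": "cnn",
        "probes": [{"mode": "trained", "n": n} for n in range(1, 9)],
        "count": 64, "epochs": 50,
    },
    "interp-full": {
        "family": "uniform", "numerosities": list(range(1, 9)),
        "holdout": [2, 5], "split_sizes": [16000, 3200, 3200],
        "frame": "paper", "model": "paper", "counter": "area",
        "probes": [{"mode": "interp", "n": 2}, {"mode": "interp", "n": 5}],
        "count": 64, "epochs": 50,
    },
    "extrap-full": {
        "family": "uniform", "numerosities": list(range(1, 6)),
        "holdout": [], "split_sizes": [16000, 3200, 3200],
        "frame": "paper", "model": "paper", "counter": "area",
        "probes": [{"mode": "extrap", "alpha": a} for a in (0.5, 1.0, 2.0)],
        "count": 64, "epochs": 50,
    },
    "pca-full": {
        "family": "uniform", "numerosities": list(range(1, 9)),
        "holdout": [], "split_sizes": [16000, 3200, 3200],
        "frame": "paper", "model": "paper", "counter": "area",
        "probes": [{"mode": "pca", "k": k, "n": n}
                   for k in (1, 2) for n in range(1, 9)],
        "count": 64, "epochs": 50,
    },
    "squares-full": {
        "family": "squares", "numerosities": list(range(1, 9)),
        "holdout": [], "split_sizes": [16000, 3200, 3200],
        "frame": "paper", "model": "paper", "counter": "area",
        "probes": [{"mode": "trained", "n": n} for n in range(1, 9)],
        "count": 64, "epochs": 50,
    },
    "mixed-full": {
        "family": "mixed", "numerosities": list(range(1, 9)),
        "holdout": [], "split_sizes": [16000, 3200, 3200],
        "frame": "paper", "model": "paper", "counter": "area",
        "probes": [{"mode": "trained", "n": n} for n in range(1, 9)],
        "count": 64, "epochs": 50,
    },
}

_PROBE_MODES = ("trained", "interp", "extrap", "pca")


def _validate_config(cfg: Dict) -> Dict:
    merged = dict(EXPERIMENT_PRESETS.get(cfg.get("preset", ""), {}))
    merged.update({k: v for k, v in cfg.items() if k != "preset"})
    required = ("family", "numerosities", "probes")
    for key in required:
        if key not in merged:
            raise ValueError(f"experiment config missing {key!r}")
    for probe in merged["probes"]:
        if probe.get("mode") not in _PROBE_MODES:
            raise ValueError(f"unknown probe {probe!r}; modes are "
                             f"{_PROBE_MODES}")
    merged.setdefault("holdout", [])
    merged.setdefault("split_sizes", [1500, 300, 300])
    merged.setdefault("frame", "tiny")
    merged.setdefault("model", "tiny")
    merged.setdefault("counter", "area")
    merged.setdefault("count", 64)
    merged.setdefault("epochs", 30)
    merged.setdefault("seed", 0)
    return merged


def run_experiment(config: Dict, out_dir, plots: bool = False) -> Path:
    """Execute a whole generation experiment into a run directory.

    Stages: build dataset (holdout numerosities excluded from training) →
    train the transformer → fit the counter → sample every probe seed →
    count → write reports.  Everything is seeded from ``config["seed"]``;
    any stage failure aborts with the stage name attached.
    """
    from . import counting, generation, stimuli, training
    from .model import PixelTransformer

    cfg = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stage = "configure"
    try:
        stage = "generate-data"
        if cfg["frame"] == "tiny":
            spec, dots = stimuli.TINY_SPEC, stimuli.TINY_PARAMS
        else:
            spec, dots = stimuli.FrameSpec(), stimuli.DotParams()
        trained_nums = [n for n in cfg["numerosities"]
                        if n not in set(cfg["holdout"])]
        bundle = stimuli.build_dataset(
            cfg["family"], trained_nums, tuple(cfg["split_sizes"]),
            master_seed=seed, spec=spec, params=dots)

        stage = "train"
        if cfg["model"] == "tiny":
            est = PixelTransformer(
                n_layers=2, d_model=32, n_heads=4,
                vocab_size=spec.intensity_levels,
                frame_shape=(spec.height, spec.width),
                numerosities=trained_nums, ff_width=128, dropout=0.0,
                batch_size=128, learning_rate=2e-3,
                epochs=int(cfg["epochs"]), patience=10, seed=seed)
        else:
            est = PixelTransformer(
                vocab_size=spec.intensity_levels,
                frame_shape=(spec.height, spec.width),
                numerosities=trained_nums, epochs=int(cfg["epochs"]),
                seed=seed)
        record = training.train(est, bundle)
        record.history.to_csv(out / "loss_curves.csv", index=False)
        est.save(out / "checkpoint.zip")

        stage = "fit-counter"
        if cfg["counter"] == "area":
            counter = counting.fit_area_counter(bundle.validation)
        elif cfg["counter"] == "cnn":
            Xc, yc = counting.make_counter_dataset(
                seed=seed, spec=spec, params=dots)
            counter, _ = counting.train_classifier_counter(
                Xc, yc, seed=seed,
                intensity_levels=spec.intensity_levels)
        else:
            raise ValueError(f"unknown counter {cfg['counter']!r}")

        stage = "sample"
        tables = est.tables_
        batches: List[SampleBatch] = []
        for i, probe in enumerate(cfg["probes"]):
            mode = probe["mode"]
            if mode == "trained":
                sos = generation.sos_trained(tables, probe["n"])
            elif mode == "interp":
                sos = generation.sos_interpolated(tables, probe["n"])
            elif mode == "extrap":
                sos = generation.sos_extrapolated(tables, probe["alpha"])
            else:
                sos = generation.sos_pca_reduced(tables, probe["k"],
                                                 probe["n"])
            batches.append(generation.spontaneous_generate(
                est, sos, count=int(cfg["count"]),
                rng=np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(100 + i,)))))

        stage = "count"
        counts = [counting.count_batch(b.images, counter) for b in batches]

        stage = "report"
        report = histogram_report(batches, counts)
        table, corr = scalar_variability_summary(report)
        emb = pca_view(tables)
        with open(out / "generation_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        with open(out / "embedding_map.json", "w") as fh:
            json.dump(emb.to_dict(), fh, indent=2)
        with open(out / "scalar_variability.json", "w") as fh:
            json.dump({"table": table.to_dict(orient="records"),
                       "correlation": corr}, fh, indent=2)
        report.summary.to_csv(out / "summary.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump({"config": cfg, "bundle": bundle.manifest,
                       "best_val_nll_per_pixel": record.best_val_nll},
                      fh, indent=2)
        if plots:
            _plot_report(report, out / "histograms.png")
    except Exception as err:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {err}") \
            from err
    return out


def _plot_report(report: GenerationReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for freq, prov in zip(report.rel_freq, report.provenances):
        ax.plot(report.bins, freq, marker="o",
                label="/".join(str(t) for t in prov))
    ax.set_xlabel("estimated numerosity")
    ax.set_ylabel("relative frequency")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
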