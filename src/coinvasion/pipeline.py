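"""End-to-end pipeline: design -> simulate (or ingest) -> RGR -> analysis.

A :class:`RunConfig` fully describes a run — species pool, design ranges,
simulator preset, observation model, analysis options, master seed — and
is serialized verbatim into the output directory, so two runs from the
same config and seed produce identical outputs (CSV floats are written at
10 significant digits).

Stages can be bypassed: a config naming CFU counts files skips the
simulator and feeds the same downstream schema, which is how real plate
-count exports enter the pipeline.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import design as dz
from . import simulate as sim
from .growth import ImputationPolicy, compute_all
from .stability import SingleVsCoModel, StabilityModel

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "summarize_by_focal",
    "FLOAT_FORMAT",
]

#: CSV float precision (significant digits) for reproducible outputs.
FLOAT_FORMAT = "%.10g"

log = logging.getLogger("coinvasion")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Serializable description of one full analysis run."""

    pool: tuple[str, ...] = dz.DEFAULT_POOL.labels
    invader_richness: tuple[int, int] = (2, 4)
    resident_richness: tuple[int, int] = (1, 4)
    replicates: int = 6
    preset: str = "stabilized"
    count_noise: str = "poisson"
    effective_sampling_fraction: float = 2e-5
    detection_limit: float = 1e3
    alpha: float = 0.05
    adjust: str = "fdr"
    imputation: str = "impute_at_limit"
    master_seed: int = 0
    compare_single: bool = True
    counts_co: str | None = None  # bypass: pre-existing CFU tables
    counts_single: str | None = None
    make_plots: bool = False
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pool"] = list(self.pool)
        d["invader_richness"] = list(self.invader_richness)
        d["resident_richness"] = list(self.resident_richness)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("pool", "invader_richness", "resident_richness"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def summarize_by_focal(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-focal-species stability bookkeeping.

    One row per focal species with its stable / tested / untestable counts;
    denominators equal the species' treatment count in the design (14 each
    in the default five-species co-invasion design).
    """
    if calls is None or len(calls) == 0:
        raise ValueError("no stability calls to summarize")
    g = calls.groupby("focal", sort=True)
    return pd.DataFrame(
        {
            "n_stable": g["stable"].sum().astype(int),
            "n_tested": g["untestable"].apply(lambda s: int((~s).sum())),
            "n_untestable": g["untestable"].sum().astype(int),
            "n_treatments": g.size(),
        }
    ).reset_index()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Returns a summary dict: stability counts, per-focal breakdown, the
    comparison's correlation/term/contrast highlights, and file paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "run_config.yaml")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except Exception as e:
        (out / "INCOMPLETE").write_text(str(e))
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    pool = dz.SpeciesPool(tuple(config.pool))
    policy = ImputationPolicy(config.imputation, config.detection_limit)
    log.info(
        "run: alpha=%g adjust=%s imputation=%s master_seed=%d preset=%s",
        config.alpha, config.adjust, config.imputation, config.master_seed,
        config.preset,
    )

    # --- stage: design -----------------------------------------------------
    try:
        co = dz.enumerate_co_invasion(
            pool, *config.invader_richness, config.replicates
        )
        single = dz.enumerate_single_invasion(
            pool, *config.resident_richness, replicates=config.replicates
        )
    except Exception as e:
        raise PipelineError(f"design stage: {e}") from e
    dz.write_design(co, pool, out / "design_co.csv")
    dz.write_design(single, pool, out / "design_single.csv")
    pairing = dz.pair_by_residents(co, single)
    log.info("design: %d co, %d single, %d pairs", len(co), len(single),
             len(pairing))

    # --- stage: simulate or ingest ----------------------------------------
    params = sim.preset(config.preset)
    scheme = sim.InoculationScheme()
    model = sim.ObservationModel(
        count_noise=config.count_noise,
        effective_sampling_fraction=config.effective_sampling_fraction,
        detection_limit=config.detection_limit,
    )
    try:
        if config.counts_co:
            counts_co = pd.read_csv(config.counts_co)
            log.info("simulator skipped; counts from %s", config.counts_co)
        else:
            counts_co = sim.generate_dataset(
                co, params, scheme, model, config.master_seed
            )
        if config.compare_single:
            if config.counts_single:
                counts_single = pd.read_csv(config.counts_single)
            elif config.counts_co:
                counts_single = None  # real co data without single counterpart
            else:
                counts_single = sim.generate_dataset(
                    single, params, scheme, model, config.master_seed + 1
                )
        else:
            counts_single = None
    except Exception as e:
        raise PipelineError(f"simulate stage: {e}") from e
    _write(counts_co, out / "counts_co.csv")
    if counts_single is not None:
        _write(counts_single, out / "counts_single.csv")

    # --- stage: growth rates ----------------------------------------------
    try:
        rgr_co = compute_all(counts_co, co, pool, policy)
        rgr_single = (
            compute_all(counts_single, single, pool, policy)
            if counts_single is not None
            else None
        )
    except Exception as e:
        raise PipelineError(f"rgr stage: {e}") from e
    _write(rgr_co, out / "rgr_co.csv")
    if rgr_single is not None:
        _write(rgr_single, out / "rgr_single.csv")

    # --- stage: stability classification -----------------------------------
    try:
        stab = StabilityModel(rgr_co).fit(alpha=config.alpha, adjust=config.adjust)
    except Exception as e:
        raise PipelineError(f"analyze stage (classify): {e}") from e
    _write(stab.calls, out / "stability_calls.csv")
    by_focal = summarize_by_focal(stab.calls)
    _write(by_focal, out / "stability_by_focal.csv")
    log.info("classify: %d tests, family size %d, %d stable",
             stab.n_tests, stab.n_tests, stab.n_stable)

    # --- stage: single vs co comparison -------------------------------------
    comparison = None
    if rgr_single is not None and pairing.pairs:
        try:
            comparison = SingleVsCoModel(
                rgr_co, rgr_single, pairing.pairs
            ).fit(alpha=config.alpha, adjust=config.adjust)
        except Exception as e:
            raise PipelineError(f"analyze stage (comparison): {e}") from e
        _write(comparison.correlations, out / "species_correlations.csv")
        _write(comparison.interaction.terms, out / "model_terms.csv")
        _write(comparison.contrasts.table, out / "contrasts.csv")

    if config.make_plots:
        import matplotlib.pyplot as plt

        ax = stab.plot()
        ax.figure.savefig(out / "rgr_by_treatment.png", dpi=150)
        plt.close(ax.figure)
        if comparison is not None:
            ax = comparison.plot()
            ax.figure.savefig(out / "single_vs_co.png", dpi=150)
            plt.close(ax.figure)

    summary = {
        "n_treatments_co": len(co),
        "n_treatments_single": len(single),
        "n_pairs": len(pairing),
        "n_tests": stab.n_tests,
        "n_stable": stab.n_stable,
        "n_unstable": stab.n_tests - stab.n_stable,
        "n_untestable": int(stab.calls["untestable"].sum()),
        "by_focal": by_focal.to_dict(orient="records"),
    }
    if comparison is not None:
        summary["common_slope"] = comparison.interaction.slope
        summary["n_significant_contrasts"] = int(
            comparison.contrasts.table["significant"].sum()
        )
        summary["spearman_rho"] = dict(
            zip(comparison.correlations["species"], comparison.correlations["rho"])
        )

    text = [
        f"coinvasion run (seed {config.master_seed}, preset {config.preset})",
        "",
        stab.summary(),
    ]
    if comparison is not None:
        text += ["", comparison.summary()]
    (out / "summary.txt").write_text("\n".join(text) + "\n")
    return summary
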