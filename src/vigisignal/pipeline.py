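"""End-to-end orchestration: simulate -> ingest -> signals -> seriousness
-> risk, with a deterministic run directory."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__, dispro, ingest, riskmodel, seriousness, synth
from .errors import PipelineError, VigisignalError
from .report import render_table, signals_frame
from .schema import VDR_AGONISTS

logger = logging.getLogger("vigisignal")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input`` points at an existing line listing, or ``simulate``
    holds a :class:`~vigisignal.synth.SynthConfig` to generate one.
    """

    outdir: str
    input: Optional[str] = None
    simulate: Optional[synth.SynthConfig] = None
    dialect: str = "csv"
    pt_soc: Optional[str] = None
    synonyms: Optional[str] = None
    drugs: Optional[Sequence[str]] = None
    level: str = "pt"
    alpha: float = 0.05
    sdr_thresholds: tuple = dispro.SDR_THRESHOLDS
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise VigisignalError("alpha must be in (0, 1)")
        if min(self.sdr_thresholds) <= 0:
            raise VigisignalError("SDR thresholds must be positive")


def _stage(name, fn, log_lines):
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - wrap with the stage name
        raise PipelineError(name, str(exc)) from exc
    return result


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write ``signals.tsv``, ``seriousness.tsv``,
    ``risk_report.tsv`` and ``run.log`` into the output directory.

    Identical configuration and seed yield byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"vigisignal {__version__}", f"seed {config.seed}"]

    def simulate():
        if config.input is not None:
            return ingest.read_line_listing(config.input, config.dialect)
        if config.simulate is None:
            raise VigisignalError("no input path and no simulation config")
        cfg = config.simulate
        cfg.seed = config.seed
        db = synth.generate_database(cfg)
        synth.write_line_listing(db, outdir / f"db.{config.dialect}", config.dialect)
        return db

    if config.input is None and config.simulate is None:
        raise PipelineError("ingest", "no input path given")
    collection = _stage("simulate" if config.input is None else "ingest",
                        simulate, log_lines)
    log_lines.append(f"input rows {len(collection)}")

    def do_ingest():
        if config.pt_soc is not None and config.synonyms is not None:
            maps = ingest.TermMaps.load(config.pt_soc, config.synonyms)
        else:
            maps = ingest.default_term_maps()
        clean, removed = ingest.deduplicate(collection)
        clean = ingest.normalize_events(clean, maps)
        return clean, removed, maps

    clean, removed, maps = _stage("ingest", do_ingest, log_lines)
    log_lines.append(f"deduplicated rows {len(clean)} (removed {removed})")

    drugs = list(config.drugs) if config.drugs else [
        d for d in VDR_AGONISTS
        if any(d in s for s in clean["suspect_drugs"])]
    if not drugs:
        raise PipelineError("signals", "no study drugs present in the data")

    def do_signals():
        frames = []
        for stratum in ("all", "serious_only"):
            results = dispro.signal_scan(
                clean, drugs, level=config.level, stratum=stratum,
                term_maps=maps, thresholds=config.sdr_thresholds)
            frames.append(signals_frame(results))
        return pd.concat(frames, ignore_index=True)

    signals = _stage("signals", do_signals, log_lines)
    (outdir / "signals.tsv").write_text(render_table(signals, "tsv"))
    log_lines.append(f"signals rows {len(signals)}")

    def do_seriousness():
        matrix = seriousness.tabulate(clean, drugs, axis="seriousness")
        resid, pvals = seriousness.adjusted_residuals(matrix)
        flags = seriousness.bonferroni_flags(pvals, config.alpha)
        out = matrix.copy()
        out["serious_pct"] = [seriousness.serious_fraction(matrix.loc[d])
                              for d in matrix.index]
        long = matrix.stack().rename("count").reset_index()
        long.columns = ["drug", "category", "count"]
        long["residual"] = resid.to_numpy().ravel()
        long["p"] = pvals.to_numpy().ravel()
        long["flag"] = flags.to_numpy().ravel()
        return out, long

    table, long = _stage("seriousness", do_seriousness, log_lines)
    serious_out = long.copy()
    serious_out["residual"] = serious_out["residual"].map(lambda v: f"{v:.3f}")
    serious_out["p"] = serious_out["p"].map(lambda v: f"{v:.3g}")
    (outdir / "seriousness.tsv").write_text(render_table(serious_out, "tsv"))
    log_lines.append(f"seriousness rows {len(long)}")

    def do_risk():
        fits = []
        for name in ("model1", "model2", "model3", "model4"):
            model = riskmodel.HypercalcemiaRiskModel.from_reports(
                clean, riskmodel.MODEL_SPECS[name])
            fits.append(model.fit())
        ranking = riskmodel.compare_models(fits)
        best = next(f for f in fits
                    if f.spec.name == ranking.iloc[0]["model"])
        return fits, ranking, best

    fits, ranking, best = _stage("risk", do_risk, log_lines)
    ors = best.odds_ratios()
    risk_rows = pd.DataFrame({
        "term": best.params.index,
        "coef": best.params.to_numpy(),
        "se": best.bse.to_numpy(),
        "z": best.zvalues.to_numpy(),
        "p": best.pvalues.to_numpy(),
        "or": ors["or"].to_numpy(),
        "ci_low": ors["ci_low"].to_numpy(),
        "ci_high": ors["ci_high"].to_numpy(),
    })
    text = render_table(ranking, "tsv") + "\n"
    text += f"best model: {best.spec.name}\n\n"
    text += render_table(risk_rows, "tsv")
    (outdir / "risk_report.tsv").write_text(text)
    log_lines.append(f"risk models fitted {len(fits)}; best {best.spec.name}")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
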