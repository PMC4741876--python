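"""Human-readable run reports with deterministic on-disk artifacts.

A report bundle contains the replicate trajectory table, the ancestry table,
the mean-field comparison, a Markdown summary and a run manifest (canonical
config hash, seed, package version) from which the run can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .calibration import SIZE_CLASSES
from .contribution import ContributionReport
from .errors import InputError


def config_hash(cfg) -> str:
    canonical = json.dumps(cfg.canonical_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def write_report(report: ContributionReport, outdir: str | Path) -> dict[str, Path]:
    """Write the report bundle into ``outdir``; returns the paths written.

    Identical configurations produce byte-identical CSV outputs.
    """
    from . import __version__

    if report.trajectory.empty or report.ancestry.empty:
        raise InputError("refusing to write a report from empty results")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["trajectory"] = out / "trajectory.csv"
    report.trajectory.to_csv(paths["trajectory"], index=False, float_format="%.10g")
    paths["ancestry"] = out / "ancestry.csv"
    report.ancestry.to_csv(paths["ancestry"], index=False, float_format="%.10g")
    paths["meanfield"] = out / "meanfield.csv"
    report.meanfield.to_csv(paths["meanfield"], index=False, float_format="%.10g")

    manifest = {
        "package": "ploidysim",
        "version": __version__,
        "seed": report.config.seed,
        "config_sha256": config_hash(report.config),
        "config": report.config.canonical_dict(),
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    mean = report.ancestry_mean
    sd = report.ancestry_sd
    mf_final = report.meanfield[report.meanfield["time"] == report.meanfield["time"].max()]
    st_mean = report.stochastic_mean_counts()
    st_final = st_mean[st_mean["time"] == st_mean["time"].max()]
    lines = [
        "# Founder-contribution run report",
        "",
        f"- package: ploidysim {__version__}",
        f"- seed: {report.config.seed}",
        f"- replicates: {report.config.replicates}",
        f"- window: day {report.config.start_days:g} to day {report.final_time:g} "
        f"(step {report.config.step_days:g} d)",
        f"- config sha256: `{config_hash(report.config)}`",
        "",
        "## Ancestry of final small cells by founder class (replicate mean)",
        "",
        "| founder class | fraction | sd |",
        "|---|---|---|",
    ]
    for c in SIZE_CLASSES:
        sd_txt = f"{sd[c]:.4f}" if sd and c in sd else "—"
        lines.append(f"| {c} | {mean.get(c, float('nan')):.4f} | {sd_txt} |")
    lines += [
        "",
        "## Final counts: stochastic replicate mean vs mean-field",
        "",
        "| class | stochastic mean | mean-field |",
        "|---|---|---|",
    ]
    for c in SIZE_CLASSES:
        s = float(st_final.loc[st_final["class"] == c, "count"].iloc[0])
        m = float(mf_final.loc[mf_final["class"] == c, "count"].iloc[0])
        lines.append(f"| {c} | {s:.2f} | {m:.2f} |")
    lines.append("")
    paths["report"] = out / "report.md"
    paths["report"].write_text("\n".join(lines))
    return paths
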