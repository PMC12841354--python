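"""Human-readable run reports and the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .prioritize import FunnelCounts, PipelineResult


@dataclass
class RunManifest:
    """Reproducibility record written next to every output set."""

    tool_version: str = __version__
    input_digests: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    stage_timings_s: dict = field(default_factory=dict)
    warning_counts: dict = field(default_factory=dict)

    def add_input(self, label: str, path) -> None:
        data = Path(path).read_bytes()
        self.input_digests[label] = hashlib.sha256(data).hexdigest()

    def write(self, path) -> None:
        payload = {
            "tool_version": self.tool_version,
            "input_digests": self.input_digests,
            "config": self.config,
            "stage_timings_s": self.stage_timings_s,
            "warning_counts": self.warning_counts,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def _funnel_lines(f: FunnelCounts) -> list:
    return [
        "## Variant funnel",
        "",
        "| stage | count |",
        "|---|---|",
        f"| variants in carriership input | {f.total_variants} |",
        f"| non-coding | {f.non_coding} |",
        f"| seen within families | {f.within_families} |",
        f"| trans-inherited after cis exclusion | {f.trans_after_cis_exclusion} |",
        f"| removed: trans in unrelated asymptomatic | {f.removed_by_unrelated_asymptomatic} |",
        f"| familial branch retained | {f.familial_retained} "
        f"({f.familial_exclusive_symptomatic} exclusive + "
        f"{f.familial_shared_with_wt} shared with WT) |",
        f"| isolated branch retained | {f.isolated_retained} "
        f"({f.isolated_exclusive} exclusive + "
        f"{f.isolated_shared_with_unrelated_wt} shared with unrelated WT) |",
        f"| total exclusive to symptomatic subjects | {f.total_exclusive_symptomatic} |",
        f"| class-3 candidates | {f.candidates_class3} |",
        f"| exclusive to asymptomatic subjects | {f.asymptomatic_exclusive} |",
        f"| observed in all subjects | {f.ubiquitous} |",
        f"| excluded by region configuration | {f.excluded_by_region} |",
    ]


def render_report(result: PipelineResult, recovery: dict | None = None) -> str:
    """Markdown report: the two-branch funnel, the candidate table, and
    per-variant rationale; a recovery-metrics block when simulation
    ground truth was supplied."""
    lines = ["# Two-hit non-coding variant prioritization report", ""]
    lines += _funnel_lines(result.funnel)
    lines += ["", "## Candidate variants (class 3, exclusive tracks)", ""]
    cand = result.candidate_frame()
    if cand.empty:
        lines.append("No class-3 candidates.")
    else:
        lines.append("| variant | rsID | MAF (%) | region | evidence |")
        lines.append("|---|---|---|---|---|")
        for row in cand.itertuples(index=False):
            lines.append(f"| {row.variant} | {row.rsid} | {row.maf_percent} | "
                         f"{row.region} | {row.evidence} |")
    if recovery is not None:
        lines += ["", "## Simulation recovery metrics", ""]
        for k in sorted(recovery):
            lines.append(f"- {k}: {recovery[k]}")
    lines += ["", "## Per-variant rationale", ""]
    for hgvs in sorted(result.results,
                       key=lambda h: result.annotations[h].sort_key()):
        r = result.results[hgvs]
        lines.append(f"- **{hgvs}** [{r.branch}/{r.category}"
                     f"{'' if not r.track else '/' + r.track}, class "
                     f"{r.path_class}]: " + "; ".join(r.rationale))
    return "\n".join(lines) + "\n"
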