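"""Reported neurocognitive comparisons and ladder reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from ..sem.fit import FitResult, fit_model
from ..sem.inference import LRTResult, format_p, likelihood_ratio_test, verdict
from ..sem.likelihood import ObservedDataset
from .builders import COG_FACTORS


@dataclass
class LadderReport:
    rows: list[dict] = field(default_factory=list)

    def add(self, comparison: str, lrt: LRTResult) -> None:
        self.rows.append(
            {
                "comparison": comparison,
                "delta_chi2": lrt.delta_chi2,
                "delta_df": lrt.delta_df,
                "p": lrt.p,
                "verdict": lrt.verdict,
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps({"comparisons": self.rows}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        header = f"{'comparison':<32} {'Δχ²':>10} {'Δdf':>4} {'p':>8}  verdict"
        lines = [header, "-" * len(header)]
        for r in self.rows:
            lines.append(
                f"{r['comparison']:<32} {r['delta_chi2']:>10.3f} "
                f"{r['delta_df']:>4d} {format_p(r['p']):>8}  {r['verdict']}"
            )
        return "\n".join(lines)


def run_reported_comparisons(
    fit_free: FitResult,
    data: ObservedDataset,
    regions: tuple[str, ...] = ("lc", "snvta"),
    domain: str = "em",
    group_suffix: str = "",
    **fit_kw,
) -> LadderReport:
    """Constrained-variant tests on a fitted neurocognitive regression model.

    For each region: all three associations fixed to zero (Δdf = 3) and
    equal across cognitive domains (Δdf = 2); across regions: equal
    association with ``domain`` (Δdf = 1).
    """
    fit_free.require_converged()
    spec = fit_free.spec
    report = LadderReport()
    starts = {lab: val for lab, val in fit_free.estimates.items()}

    def refit(new_spec):
        return fit_model(new_spec, data, start_values=starts, **fit_kw)

    for region in regions:
        labels = [
            f"beta.{cf}.{region}_multi{group_suffix}" for cf in COG_FACTORS
        ]
        zero_spec = spec
        for lab in labels:
            zero_spec = zero_spec.fix(lab, 0.0)
        lrt = likelihood_ratio_test(fit_free, refit(zero_spec), labels)
        report.add(f"{region}: all associations zero", lrt)
        eq_spec = spec.constrain_equal(labels, f"beta.eq.{region}")
        lrt = likelihood_ratio_test(fit_free, refit(eq_spec), labels)
        report.add(f"{region}: equal across domains", lrt)
    if len(regions) == 2:
        labels = [
            f"beta.{domain}.{r}_multi{group_suffix}" for r in regions
        ]
        eq_spec = spec.constrain_equal(labels, f"beta.{domain}.eq")
        lrt = likelihood_ratio_test(fit_free, refit(eq_spec), labels)
        report.add(f"{domain}: equal across regions", lrt)
    return report
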