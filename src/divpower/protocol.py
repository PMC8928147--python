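"""Standardised power-analysis protocols.

Studies routinely omit the effect sizes and assumptions behind their
sample-size choices; a fixed protocol layout (modelled on the protocol
sheet of the G*Power software) makes the calculation auditable.  Two
renderers are provided — univariate (alpha diversity, t/WMW machinery)
and multivariate (beta diversity, PERMANOVA by resampling) — plus a
parser that recovers every input field from the rendered text, and a
machine-readable JSON twin.
"""

from __future__ import annotations

import json
import re

from .community import ValidationError
from .power import PowerSolution, PowerSpec

_TEST_TITLES = {
    "t_test": "t-tests - Means: Difference between two independent means",
    "wmw": "t-tests - Means: Wilcoxon-Mann-Whitney test (two groups)",
    "anova": "F-tests - ANOVA: Fixed effects, omnibus, one-way",
}

_KINDS = ("a_priori", "post_hoc")


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e6:
            return str(int(value)) if value.is_integer() and abs(value) >= 1 else f"{value:g}"
        return f"{value:g}"
    return str(value)


def _block(pairs):
    return [f"\t{label}\t= {_fmt(value)}" for label, value in pairs]


def render_protocol_univariate(solution: PowerSolution, spec: PowerSpec,
                               kind: str = "a_priori",
                               metric_name: str = "Shannon",
                               target_power: float = None) -> str:
    """Render a Table-style univariate (alpha diversity) protocol."""
    if kind not in _KINDS:
        raise ValidationError(f"kind must be one of {_KINDS}")
    lines = [
        "Power analysis protocol: univariate case - alpha diversity",
        _TEST_TITLES[spec.test],
    ]
    if spec.test == "wmw":
        lines.append("Options:\tA.R.E. method")
    analysis = ("A priori: compute required sample size"
                if kind == "a_priori"
                else "Post hoc: compute achieved power")
    lines.append(f"Analysis:\t{analysis}")

    inputs = [
        ("Tail(s)", "One" if spec.tails == "one" else "Two"),
        ("Parent distribution", spec.parent_distribution.capitalize()),
        ("Effect size d", spec.effect),
        ("Alpha metric", metric_name),
        ("alpha err prob", spec.alpha_level),
    ]
    if kind == "a_priori":
        if target_power is None:
            raise ValidationError("a-priori protocol needs target_power")
        inputs.append(("Power (1-beta err prob)", target_power))
        inputs.append(("Allocation ratio N2/N1", spec.allocation_ratio))
    else:
        inputs.append(("Sample size group 1", solution.n1))
        inputs.append(("Sample size group 2", solution.n2))
    lines.append("Input:")
    lines.extend(_block(inputs))

    outputs = [
        ("Noncentrality parameter delta", round(solution.noncentrality, 6)),
        ("Critical t", round(solution.critical_value, 6)),
        ("df", round(solution.df, 1)),
    ]
    if kind == "a_priori":
        outputs.extend([
            ("Sample size group 1", solution.n1),
            ("Sample size group 2", solution.n2),
            ("Total sample size", solution.N),
            ("Actual power", round(solution.achieved_power, 3)),
        ])
    else:
        outputs.append(("Achieved power", round(solution.achieved_power, 4)))
    lines.append("Output:")
    lines.extend(_block(outputs))
    return "\n".join(lines) + "\n"


def render_protocol_multivariate(curve, effects, scheme, n: int,
                                 metric_name: str, n_taxa: int,
                                 n_permutations: int = 9999,
                                 n_groups: int = 2) -> str:
    """Render a Table-style multivariate (beta diversity) protocol.

    ``curve`` and ``effects`` come from
    :func:`divpower.empirical.empirical_power_beta` with
    ``collect_effects=True``; ``n`` selects the per-group size row.
    """
    if scheme.K < 1 or len(curve.points) == 0:
        raise ValidationError("protocol needs at least one iteration")
    point = curve.points.loc[curve.points["n"] == n]
    erow = effects.loc[effects["n"] == n]
    if point.empty or erow.empty:
        raise ValidationError(f"n={n} not on the curve grid")
    point, erow = point.iloc[0], erow.iloc[0]

    lines = [
        "Power analysis protocol: multivariate case - beta diversity",
        "Test - PERMANOVA",
        f"Options:\t{n_permutations:,} permutation",
        f"\t{scheme.K} iterations",
        "Analysis:\tCompute achievable power",
        "Input:",
    ]
    lines.extend(_block([
        ("Beta metric", metric_name),
        ("alpha err prob", scheme.alpha_level),
        ("Number of groups", n_groups),
        ("Number of taxa", n_taxa),
        ("Sample size group 1", int(n)),
        ("Sample size group 2", int(n)),
    ]))
    lines.append("Output:")
    lines.extend(_block([
        ("Observed effect size (average) omega2", round(erow["omega2_mean"], 6)),
        ("Min\\Max effect size omega2",
         f"{erow['omega2_min']:.6f}\\{erow['omega2_max']:.6f}"),
        ("Observed effect size (average) f2", round(erow["f2_mean"], 6)),
        ("Min\\Max effect size f2",
         f"{erow['f2_min']:.6f}\\{erow['f2_max']:.6f}"),
        ("Numerator df", n_groups - 1),
        ("Denominator df", int(n_groups * n - n_groups)),
        ("Power (1-beta err prob)", round(point["EPr"], 4)),
    ]))
    return "\n".join(lines) + "\n"


def parse_protocol(text: str) -> dict:
    """Recover the labelled fields of a rendered protocol as a dict."""
    fields = {}
    for line in text.splitlines():
        m = re.match(r"\t(.+?)\t= (.*)$", line)
        if m:
            label, value = m.group(1), m.group(2)
            try:
                fields[label] = float(value) if "." in value or value.isdigit() \
                    else value
            except ValueError:
                fields[label] = value
        elif line.startswith(("Analysis:", "Options:")):
            key, _, val = line.partition("\t")
            if val:
                fields.setdefault(key.rstrip(":").lower(), []).append(val)
    return fields


def protocol_json(text: str) -> str:
    """Machine-readable twin of a rendered protocol."""
    return json.dumps(parse_protocol(text), indent=2, default=str)
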