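"""Network assembly from the DE-YOLOv13-S layer table and parameter audit.

The shipped text fixture (``data/de_yolov13_s.tsv``) mirrors the published
per-layer table: row id, source row(s), expected trainable-parameter count,
module name, and the literal argument tuple.  :func:`build_network` turns
the rows into a runnable graph; :func:`verify_params` compares the actual
per-row scalar counts against the expected ones.

Layer routing follows the usual detector convention: ``from = -1`` takes
the previous row's output; a list of ids feeds a multi-input block
(concatenation, gated tunnels, the multi-scale fusion block, the detection
head).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .nn.autograd import Tensor, no_grad
from .nn.module import Module, ModuleList, ConvBlock, seed_all
from .nn import blocks as B
from .dynamic_conv import DynamicConv, DynamicConvC3k2
from .emca import EMCA

__all__ = [
    "LayerSpec", "parse_spec", "default_spec_text", "load_default_specs",
    "Network", "build_network", "verify_params", "format_param_report",
]


@dataclass
class LayerSpec:
    id: int
    src: int | list[int]
    module_name: str
    arguments: list = field(default_factory=list)
    expected_params: int | None = None

    @property
    def inputs(self) -> list[int]:
        return self.src if isinstance(self.src, list) else [self.src]


def default_spec_text() -> str:
    return resources.files("teayolo.data").joinpath("de_yolov13_s.tsv").read_text()


def _parse_literal(text: str):
    return ast.literal_eval(text.replace("‘", "'").replace("’", "'")
                            .replace("−", "-"))


def parse_spec(rows) -> list[LayerSpec]:
    """Parse layer rows (text block, lines, or pre-split field tuples).

    Rows must be consecutively numbered from 0 and may only reference
    earlier rows (or -1 for the previous one).
    """
    if isinstance(rows, str):
        rows = rows.splitlines()
    specs: list[LayerSpec] = []
    for raw in rows:
        if isinstance(raw, str):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split(None, 4)
        else:
            fields = list(raw)
        if len(fields) != 5:
            raise ValueError(f"malformed row (need 5 fields): {raw!r}")
        try:
            lid = int(fields[0])
            src = _parse_literal(str(fields[1]))
            params = str(fields[2]).replace(",", "")
            expected = None if params in ("", "-") else int(params)
            name = str(fields[3]).strip()
            args = _parse_literal(str(fields[4]))
        except (ValueError, SyntaxError) as e:
            raise ValueError(f"malformed row {fields[0]!r}: {e}") from e
        if lid != len(specs):
            raise ValueError(f"row id {lid} out of order (expected {len(specs)})")
        for ref in ([src] if isinstance(src, int) else src):
            if ref != -1 and not 0 <= ref < lid:
                raise ValueError(f"row {lid} references row {ref}, which is not earlier")
        specs.append(LayerSpec(lid, src, name, list(args), expected))
    return specs


def load_default_specs() -> list[LayerSpec]:
    return parse_spec(default_spec_text())


_REGISTRY = {
    "Conv": ConvBlock,
    "DynamicConv": DynamicConv,
    "DynamicConv-C3k2": DynamicConvC3k2,
    "A2C2f": B.A2C2f,
    "HyperACE": B.HyperACE,
    "Upsample": B.Upsample,
    "DownsampleConv": B.DownsampleConv,
    "FullPAD_Tunnel": B.FullPAD_Tunnel,
    "Concat": B.Concat,
    "EMCA": EMCA,
    "Detect": B.Detect,
}

_MULTI_INPUT = {"HyperACE", "FullPAD_Tunnel", "Concat", "Detect"}


class Network(Module):
    """Runnable layer graph assembled from a list of :class:`LayerSpec`."""

    def __init__(self, specs: Sequence[LayerSpec]):
        super().__init__()
        self.specs = list(specs)
        layers = []
        for spec in self.specs:
            if spec.module_name not in _REGISTRY:
                raise ValueError(f"row {spec.id}: unknown module {spec.module_name!r}")
            layers.append(_REGISTRY[spec.module_name](*spec.arguments))
        self.layers = ModuleList(layers)
        # rows whose outputs later rows (other than the next) still need
        needed = set()
        for spec in self.specs:
            for ref in spec.inputs:
                if ref != -1:
                    needed.add(ref)
        self._save = needed
        self.detect = layers[-1] if isinstance(layers[-1], B.Detect) else None

    def forward(self, x):
        saved: dict[int, Tensor] = {}
        prev = x
        for spec, layer in zip(self.specs, self.layers):
            if spec.module_name in _MULTI_INPUT:
                inp = [prev if ref == -1 else saved[ref] for ref in spec.inputs]
            else:
                ref = spec.src if isinstance(spec.src, int) else spec.src[0]
                inp = prev if ref == -1 else saved[ref]
            prev = layer(inp)
            if spec.id in self._save:
                saved[spec.id] = prev
        return prev

    def predict(self, x, conf_threshold=0.25):
        with no_grad():
            self.eval()
            outputs = self.forward(x)
        return self.detect.decode(outputs, conf_threshold=conf_threshold)


def build_network(specs: Sequence[LayerSpec] | None = None, seed: int | None = None) -> Network:
    """Assemble the network; a given seed makes initialization reproducible."""
    if specs is None:
        specs = load_default_specs()
    if seed is not None:
        seed_all(seed)
    return Network(specs)


def verify_params(net: Network, specs: Sequence[LayerSpec] | None = None):
    """Per-row actual-vs-expected parameter counts.

    Returns a list of dict rows plus a totals entry; mismatches carry a
    nonzero ``delta``.  Report-only: nothing is raised.
    """
    specs = list(specs) if specs is not None else net.specs
    rows = []
    total_actual = total_expected = 0
    for spec, layer in zip(specs, net.layers):
        actual = layer.num_params()
        expected = spec.expected_params
        total_actual += actual
        if expected is not None:
            total_expected += expected
        rows.append({
            "id": spec.id, "module": spec.module_name,
            "arguments": spec.arguments,
            "expected": expected, "actual": actual,
            "delta": None if expected is None else actual - expected,
        })
    return {
        "rows": rows,
        "total_actual": total_actual,
        "total_expected": total_expected,
        "total_trainable": net.num_params(trainable_only=True),
        "mismatches": [r for r in rows if r["delta"] not in (None, 0)],
    }


def format_param_report(report) -> str:
    lines = [f"{'id':>3} {'module':<18} {'expected':>10} {'actual':>10} {'delta':>7}"]
    for r in report["rows"]:
        exp = "-" if r["expected"] is None else f"{r['expected']:,}"
        delta = "" if r["delta"] in (None, 0) else f"{r['delta']:+d}"
        lines.append(f"{r['id']:>3} {r['module']:<18} {exp:>10} {r['actual']:>10,} {delta:>7}")
    lines.append(f"{'':>3} {'TOTAL':<18} {report['total_expected']:>10,} "
                 f"{report['total_actual']:>10,}")
    lines.append(f"trainable (gradient-carrying) scalars: {report['total_trainable']:,}")
    return "\n".join(lines)
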