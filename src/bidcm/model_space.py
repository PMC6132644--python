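"""Enumeration of the candidate model space and its family partition.

Models share fixed bidirectional intrinsic DLPFC<->striatum connections and
vary along two axes:

* modulation pattern -- which of the 4 (encoding input x directed
  connection) modulations are enabled: {EN, EP} x {DLPFC->striatum,
  striatum->DLPFC}, all 2^4 = 16 on/off combinations including none.
  The modulation pattern defines the model family.
* driving-input pattern -- 4 routing flags (encoding bundle -> DLPFC,
  encoding bundle -> striatum, retrieval bundle -> DLPFC, retrieval
  bundle -> striatum); all 2^4 - 1 = 15 non-empty combinations (a model
  with no input at all is excluded).

The cross product gives 16 x 15 = 240 models in 16 families of 15.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import ModelStructure

__all__ = ["ModelSpace", "enumerate_models", "describe_model",
           "FULL_MODULATION_FAMILY", "WINNER_INPUT_PATTERN"]

_SCHEMES = ("bundled",)

#: Family index (bit pattern) of the full-modulation family.
FULL_MODULATION_FAMILY = 15

#: Input routing of the winning model: all conditions to DLPFC only.
WINNER_INPUT_PATTERN = (True, False, True, False)

_B_LABELS = ("EN: DLPFC->Striatum", "EN: Striatum->DLPFC",
             "EP: DLPFC->Striatum", "EP: Striatum->DLPFC")
_C_LABELS = ("encoding->DLPFC", "encoding->Striatum",
             "retrieval->DLPFC", "retrieval->Striatum")


def _bits(value: int, width: int = 4) -> tuple[bool, ...]:
    """Most-significant-bit-first boolean tuple of ``value``."""
    return tuple(bool((value >> (width - 1 - i)) & 1) for i in range(width))


@dataclass
class ModelSpace:
    """All candidate models, with the family partition by modulation pattern."""

    models: list[ModelStructure]
    input_scheme: str = "bundled"
    families: dict[int, list[int]] = field(init=False)

    def __post_init__(self) -> None:
        self.families = {}
        for m in self.models:
            self.families.setdefault(m.family_id, []).append(m.model_id)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def model(self, model_id: int) -> ModelStructure:
        m = self.models[model_id]
        assert m.model_id == model_id
        return m

    def family_partition(self) -> dict[int, list[int]]:
        """family_id -> sorted model ids (a copy safe to mutate)."""
        return {k: sorted(v) for k, v in self.families.items()}

    def find(self, b_masks, c_mask) -> int:
        """Model id with the given modulation and input masks."""
        key = (tuple(tuple(b) for b in b_masks), tuple(c_mask))
        for m in self.models:
            if (tuple(tuple(b) for b in m.b_masks), tuple(m.c_mask)) == key:
                return m.model_id
        raise KeyError(f"no model with masks {key}")

    @property
    def winner_model_id(self) -> int:
        """The model reported best for this paradigm: full modulation,
        all four condition inputs routed to DLPFC only."""
        return self.find(((True, True), (True, True)), WINNER_INPUT_PATTERN)

    # -- serialisation ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "input_scheme": self.input_scheme,
            "models": [{"model_id": m.model_id, "family_id": m.family_id,
                        "b_masks": [list(b) for b in m.b_masks],
                        "c_mask": list(m.c_mask)} for m in self.models],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def masks_frame(self) -> pd.DataFrame:
        """Per-model truth table of modulation and input flags."""
        rows = []
        for m in self.models:
            row = {"model_id": m.model_id, "family_id": m.family_id}
            flat = [b for pair in m.b_masks for b in pair]
            row.update({f"b_{lbl}": int(v) for lbl, v in zip(_B_LABELS, flat)})
            row.update({f"c_{lbl}": int(v) for lbl, v in zip(_C_LABELS, m.c_mask)})
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_models(scheme: str = "bundled") -> ModelSpace:
    """Enumerate the full model space under the given input scheme.

    The default (and only built-in) scheme, ``"bundled"``, routes the
    encoding and retrieval condition bundles independently to each region
    (4 binary flags, the all-off combination excluded), which yields 15
    driving-input variants including an "all conditions to DLPFC only"
    member.  Model ids are dense and lexicographic: modulation bits (major)
    then input bits.
    """
    if scheme not in _SCHEMES:
        raise ValueError(
            f"unknown input scheme {scheme!r}; supported: {_SCHEMES}")
    models = []
    model_id = 0
    for fam in range(16):
        mb = _bits(fam)
        b_masks = ((mb[0], mb[1]), (mb[2], mb[3]))  # (EN, EP) x (d->s, s->d)
        for inp in range(1, 16):
            models.append(ModelStructure(
                b_masks=b_masks, c_mask=_bits(inp),
                model_id=model_id, family_id=fam))
            model_id += 1
    return ModelSpace(models=models, input_scheme=scheme)


def describe_model(space: ModelSpace, model_id: int) -> str:
    """Human-readable summary of one model's structure."""
    if not 0 <= model_id < space.n_models:
        raise KeyError(f"unknown model id {model_id}")
    m = space.model(model_id)
    flat = [b for pair in m.b_masks for b in pair]
    mods = [lbl for lbl, v in zip(_B_LABELS, flat) if v]
    inps = [lbl for lbl, v in zip(_C_LABELS, m.c_mask) if v]
    lines = [f"model {m.model_id} (family {m.family_id})"]
    if all(flat):
        lines.append("modulation of both connections by EN and EP"
                     " (full modulation)")
    elif mods:
        lines.append("modulation: " + "; ".join(mods))
    else:
        lines.append("no modulation")
    if m.c_mask == WINNER_INPUT_PATTERN:
        lines.append("input from all four conditions to DLPFC only")
    else:
        lines.append("input: " + "; ".join(inps))
    if all(flat) and m.c_mask == WINNER_INPUT_PATTERN:
        lines.append("[reported winning model for this paradigm]")
    return "\n".join(lines)
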