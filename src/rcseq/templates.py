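"""Loading template/product collections from YAML documents.

The package ships one built-in collection covering the barcoded one-pot
templates (A–D, circular and linear) and the two phase-shifted products of
the doubly-primed branched circle (I/II).  The position-6 and position-9
barcodes of the built-in one-pot templates are synthetic placeholders (see
the YAML header); real runs can supply their own document with the same
schema.

Schema::

    alphabet: [CTG, ATA, ...]      # optional, defaults to the 14-triplet set
    primer: GAAGAACTG              # collection-wide default primer
    adapter: GTCGAATAT             # 3' adapter prefix
    templates:
      <name>: {topology: circular|linear, circle_len_nt: int,
               primer: str, expected: [triplets...],
               barcodes: {position: triplet}, full_circle_override: int}
    products:
      <name>: same fields as a circular template
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .model import (
    DEFAULT_ALPHABET,
    ConfigError,
    ProductSpec,
    TemplateSpec,
    Triplet,
    TripletAlphabet,
)

__all__ = ["TemplateCollection", "load_templates", "builtin_templates"]

_BUILTIN = "templates_with_synthetic_barcodes.yaml"


@dataclass(frozen=True)
class TemplateCollection:
    """Named templates and branched products sharing a primer and adapter."""

    templates: Mapping[str, TemplateSpec]
    products: Mapping[str, ProductSpec]
    primer: str
    adapter: str
    alphabet: TripletAlphabet

    def __getitem__(self, name: str) -> TemplateSpec:
        return self.templates[name]

    def barcode_map(self, position: int = 3, suffix: str = "_circular") -> dict[Triplet, str]:
        """Map each template's barcode at ``position`` to a short template
        label (the name with ``suffix`` stripped), for read classification."""
        out: dict[Triplet, str] = {}
        for name, spec in self.templates.items():
            if not name.endswith(suffix):
                continue
            bc = spec.barcode_positions.get(position)
            if bc is None:
                continue
            label = name[: -len(suffix)] if suffix else name
            if bc in out:
                raise ConfigError(f"barcode {bc} at position {position} is not unique")
            out[bc] = label
        return out


def _spec_from_dict(name: str, d: Mapping, alphabet: TripletAlphabet, default_primer: str) -> TemplateSpec:
    return TemplateSpec(
        name=name,
        topology=d["topology"],
        primer_seq=d.get("primer", default_primer),
        expected=tuple(d.get("expected", ())),
        circle_len_nt=d.get("circle_len_nt"),
        barcode_positions=d.get("barcodes", {}),
        full_circle_override=d.get("full_circle_override"),
        alphabet=alphabet,
    )


def load_templates(source: Union[str, Path, Mapping]) -> TemplateCollection:
    """Parse a template collection from a YAML path or an already-parsed dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ConfigError("template document must be a mapping")
    alphabet = (
        TripletAlphabet(doc["alphabet"]) if "alphabet" in doc else DEFAULT_ALPHABET
    )
    primer = doc.get("primer", "")
    adapter = doc.get("adapter", "GTCGAATAT")
    templates = {
        name: _spec_from_dict(name, d, alphabet, primer)
        for name, d in (doc.get("templates") or {}).items()
    }
    products = {
        name: ProductSpec(name=name, template=_spec_from_dict(name, d, alphabet, primer))
        for name, d in (doc.get("products") or {}).items()
    }
    return TemplateCollection(
        templates=templates, products=products, primer=primer, adapter=adapter, alphabet=alphabet
    )


def builtin_templates() -> TemplateCollection:
    """The bundled one-pot (A–D) and branched (I/II) template collection."""
    ref = resources.files("rcseq.data").joinpath(_BUILTIN)
    with resources.as_file(ref) as path:
        return load_templates(path)
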