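"""Built-in cell-type synonym table shared by the offline embedding provider
and the alias generator.

The table is intentionally small: it only needs to cover the vocabulary of
the bundled simulator plus a handful of common immune/pancreas/skin types so
that alias experiments have realistic alternative nomenclature to draw from.
"""

from __future__ import annotations

import re

# canonical display name -> list of alias display names
SYNONYMS: dict[str, list[str]] = {
    "T cell": ["T lymphocyte", "T-cell"],
    "B cell": ["B lymphocyte", "B-cell"],
    "NK cell": ["natural killer cell"],
    "dendritic cell": ["DC"],
    "macrophage": ["tissue macrophage"],
    "monocyte": ["classical monocyte"],
    "plasma cell": ["plasmablast"],
    "alpha cell": ["pancreatic alpha cell"],
    "beta cell": ["pancreatic beta cell"],
    "delta cell": ["pancreatic delta cell"],
    "acinar cell": ["pancreatic acinar cell"],
    "ductal cell": ["pancreatic ductal cell"],
    "fibroblast": ["stromal fibroblast"],
    "keratinocyte": ["epidermal keratinocyte"],
    "endothelial cell": ["vascular endothelial cell"],
    "mast cell": ["mastocyte"],
}

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Trim, collapse internal whitespace and lowercase a label for keying."""
    return _WS.sub(" ", str(label).strip()).lower()


# normalized form (canonical or alias) -> canonical display name
CANONICAL: dict[str, str] = {}
for _canon, _aliases in SYNONYMS.items():
    CANONICAL[normalize_label(_canon)] = _canon
    for _a in _aliases:
        CANONICAL[normalize_label(_a)] = _canon


def canonical_form(label: str) -> str:
    """Map a label to its canonical synonym-group representative (normalized).

    Unknown labels map to their own normalized form.
    """
    norm = normalize_label(label)
    return normalize_label(CANONICAL.get(norm, norm))


def is_synonym_alias(label: str) -> bool:
    """True when the label is a known alias distinct from its canonical form."""
    norm = normalize_label(label)
    return norm in CANONICAL and normalize_label(CANONICAL[norm]) != norm
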