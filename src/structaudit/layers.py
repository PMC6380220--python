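"""Standard InChI layer parsing, Hill formulas, and charge arithmetic.

An InChI string is decomposed into its semantic layers (formula, /c heavy-atom
connectivity, /h hydrogen placement, /q net intrinsic charge, /p protonation
delta, /b double-bond geometry, /t chirality, /m /s stereo bookkeeping, /i
isotopes). The core-parent vs charged-species arithmetic lives here:

    H(charged species) = H(core parent) + proton_delta
    charge(charged species) = net_charge + proton_delta

Input strings coming from typeset sources may carry inserted whitespace and
emphasis markers; :func:`normalize_inchi_text` strips those before parsing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .mol import ELEMENTS

__all__ = [
    "InChIError",
    "InChILayers",
    "HillFormula",
    "normalize_inchi_text",
    "parse_inchi",
    "serialize",
    "net_charge",
    "proton_delta",
    "core_parent_formula",
    "charged_species_formula",
    "hill_format",
    "parse_formula_string",
    "has_ambiguous_stereo",
    "expand_components",
]

_MAIN_LAYER_ORDER = "chqpbtms"  # after the formula layer; /i opens the isotope section


class InChIError(ValueError):
    """Malformed InChI or formula text."""


@dataclass
class HillFormula:
    """Element composition in Hill convention plus a net charge."""

    composition: dict[str, int]
    charge: int = 0

    @property
    def text(self) -> str:
        return hill_format(self.composition, self.charge)

    def __eq__(self, other) -> bool:  # order-insensitive on composition
        return (
            isinstance(other, HillFormula)
            and dict(self.composition) == dict(other.composition)
            and self.charge == other.charge
        )


@dataclass
class InChILayers:
    version: str
    standard: bool
    formula_text: str
    formula: tuple[dict[str, int], ...]  # one composition per "."-component
    c_layer: str = ""
    h_layer: str = ""
    q_layer: str = ""
    p_layer: str = ""
    b_layer: str = ""
    t_layer: str = ""
    m_layer: str = ""
    s_layer: str = ""
    i_layer: str = ""
    extras: dict[str, str] = field(default_factory=dict)
    q_values: tuple[int, ...] = ()
    p_values: tuple[int, ...] = ()
    source: str = ""

    @property
    def n_components(self) -> int:
        return len(self.formula)


def normalize_inchi_text(text: str) -> str:
    """Undo typesetting damage: inserted whitespace, emphasis markers, quotes."""
    cleaned = re.sub(r"\s+", "", text)
    # doubled asterisks are typeset emphasis; a single '*' is the InChI
    # repetition operator and must survive
    cleaned = cleaned.replace("**", "").replace("−", "-")
    cleaned = cleaned.strip("\"'“”‘’")
    cleaned = cleaned.rstrip(".,;")
    return cleaned


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_one_composition(text: str) -> dict[str, int]:
    comp: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m:
            raise InChIError(f"cannot read element token at {text[pos:]!r} in {text!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise InChIError(f"unknown element symbol {sym!r} in {text!r}")
        comp[sym] = comp.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if not comp:
        raise InChIError(f"empty composition in {text!r}")
    return comp


def _parse_formula_layer(text: str) -> tuple[dict[str, int], ...]:
    comps: list[dict[str, int]] = []
    for part in text.split("."):
        if not part:
            raise InChIError(f"empty formula component in {text!r}")
        m = re.match(r"(\d+)([A-Z].*)", part)
        mult, body = (int(m.group(1)), m.group(2)) if m else (1, part)
        comp = _parse_one_composition(body)
        comps.extend(dict(comp) for _ in range(mult))
    return tuple(comps)


def expand_components(layer_text: str) -> list[str]:
    """Split a layer on ';' and expand 'n*' repetition shorthand."""
    if layer_text == "":
        return []
    out: list[str] = []
    for seg in layer_text.split(";"):
        m = re.match(r"(\d+)\*(.*)", seg)
        if m:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(seg)
    return out


def _parse_signed_values(layer_text: str, what: str) -> tuple[int, ...]:
    vals: list[int] = []
    for seg in expand_components(layer_text):
        if seg == "":
            vals.append(0)
            continue
        if not re.fullmatch(r"[+-]\d+", seg):
            raise InChIError(f"unparseable {what} component {seg!r} in {layer_text!r}")
        vals.append(int(seg))
    return tuple(vals)


def parse_inchi(text: str) -> InChILayers:
    """Parse a (possibly typeset-damaged) InChI string into its layers.

    Non-standard "InChI=1/" strings parse with ``standard=False`` — they are
    flagged, never silently compared as standard. Unknown layers land in
    ``extras``; everything from ``/i`` onward is kept verbatim as the isotope
    section (it may contain its own sub-layers).
    """
    norm = normalize_inchi_text(text)
    if not norm.startswith("InChI="):
        raise InChIError(f"not an InChI string: {text[:40]!r}")
    body = norm[len("InChI="):]
    segments = body.split("/")
    version = segments[0]
    if not version:
        raise InChIError("missing version segment")
    standard = version == "1S"
    if len(segments) < 2 or not segments[1]:
        raise InChIError("missing formula layer")
    formula_text = segments[1]
    formula = _parse_formula_layer(formula_text)

    layers: dict[str, str] = {}
    extras: dict[str, str] = {}
    i_parts: list[str] = []
    in_isotope = False
    for seg in segments[2:]:
        if not seg:
            continue
        prefix = seg[0]
        if in_isotope:
            i_parts.append(seg)
            continue
        if prefix == "i":
            in_isotope = True
            i_parts.append(seg[1:])
        elif prefix in _MAIN_LAYER_ORDER and prefix not in layers:
            layers[prefix] = seg[1:]
        else:
            extras[seg[:1]] = seg[1:]
            if prefix in ("f", "r"):
                standard = False

    q_layer = layers.get("q", "")
    p_layer = layers.get("p", "")
    return InChILayers(
        version=version,
        standard=standard,
        formula_text=formula_text,
        formula=formula,
        c_layer=layers.get("c", ""),
        h_layer=layers.get("h", ""),
        q_layer=q_layer,
        p_layer=p_layer,
        b_layer=layers.get("b", ""),
        t_layer=layers.get("t", ""),
        m_layer=layers.get("m", ""),
        s_layer=layers.get("s", ""),
        i_layer="/".join(i_parts),
        extras=extras,
        q_values=_parse_signed_values(q_layer, "/q"),
        p_values=_parse_signed_values(p_layer, "/p"),
        source=norm,
    )


def serialize(layers: InChILayers) -> str:
    """Emit the layers in standard order; parse∘serialize is the identity."""
    if not layers.formula_text:
        raise InChIError("cannot serialize layers without a formula")
    parts = [f"InChI={layers.version}", layers.formula_text]
    raw = {
        "c": layers.c_layer,
        "h": layers.h_layer,
        "q": layers.q_layer,
        "p": layers.p_layer,
        "b": layers.b_layer,
        "t": layers.t_layer,
        "m": layers.m_layer,
        "s": layers.s_layer,
    }
    for key in _MAIN_LAYER_ORDER:
        if raw[key]:
            parts.append(key + raw[key])
    for key, value in layers.extras.items():
        parts.append(key + value)
    if layers.i_layer:
        parts.append("i" + layers.i_layer)
    return "/".join(parts)


def net_charge(layers: InChILayers) -> int:
    """Sum of the /q layer over components; absent layer means neutral."""
    return sum(layers.q_values)


def proton_delta(layers: InChILayers) -> int:
    """Sum of the /p layer over components; absent layer means no (de)protonation."""
    return sum(layers.p_values)


def _merged_composition(layers: InChILayers) -> dict[str, int]:
    merged: dict[str, int] = {}
    for comp in layers.formula:
        for el, n in comp.items():
            merged[el] = merged.get(el, 0) + n
    return merged


def core_parent_formula(layers: InChILayers) -> HillFormula:
    """Composition before (de)protonation, carrying the intrinsic /q charge."""
    return HillFormula(composition=_merged_composition(layers), charge=net_charge(layers))


def charged_species_formula(layers: InChILayers) -> HillFormula:
    """Composition of the species as drawn: core H shifted by /p, charge q+p."""
    comp = _merged_composition(layers)
    p = proton_delta(layers)
    if p:
        h = comp.get("H", 0) + p
        if h < 0:
            raise InChIError(f"/p removes {-p} protons but core has only {comp.get('H', 0)} H")
        if h == 0:
            comp.pop("H", None)
        else:
            comp["H"] = h
    return HillFormula(composition=comp, charge=net_charge(layers) + p)


def hill_format(composition: dict[str, int], charge: int = 0) -> str:
    """Hill convention: C, H, then alphabetical; fully alphabetical without C."""
    if not composition:
        raise InChIError("empty composition")
    if any(n < 1 for n in composition.values()):
        raise InChIError(f"non-positive count in {composition!r}")
    if "C" in composition:
        def key(el: str):
            return (0, "") if el == "C" else (1, "") if el == "H" else (2, el)
    else:
        def key(el: str):
            return (0, el)
    parts = []
    for el in sorted(composition, key=key):
        n = composition[el]
        parts.append(el if n == 1 else f"{el}{n}")
    body = "".join(parts)
    if charge == 0:
        return body
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return body + (sign if mag == 1 else f"{sign}{mag}")


def _merge_formula_components(body: str) -> dict[str, int]:
    merged: dict[str, int] = {}
    for comp in _parse_formula_layer(body):
        for el, n in comp.items():
            merged[el] = merged.get(el, 0) + n
    return merged


def parse_formula_string(text: str) -> tuple[dict[str, int], int, bool]:
    """Parse a molecular-formula string with an optional charge suffix.

    Accepts the suffix dialects ``+``, ``-``, ``+2``, ``-2``, ``2+``, ``2-``.
    A bare trailing sign means ±1 and any digits before it stay with the
    element count ("C2H6NO2+" is O2, charge +1); the digit-first reading of
    the digits as a charge magnitude is tried only when the count reading
    fails to parse. Multi-component formulas ("."-separated, optional leading
    multipliers) are merged by summation.
    Returns ``(composition, charge, was_charged)``.
    """
    if not text or not text.strip():
        raise InChIError("empty formula string")
    norm = re.sub(r"\s+", "", text).replace("−", "-")
    while norm.startswith("(") and norm.endswith(")"):
        norm = norm[1:-1]
    if not norm:
        raise InChIError(f"empty formula string {text!r}")

    candidates: list[tuple[str, int, bool]] = []  # (body, charge, was_charged)
    m = re.search(r"([+-])(\d*)$", norm)
    if m:
        sign, digits = m.group(1), m.group(2)
        mag = int(digits) if digits else 1
        body = norm[: m.start()]
        if not digits:
            # bare sign: prefer digits-before-it as counts, fall back to
            # reading them as the charge magnitude ("2+" dialect)
            candidates.append((body, 1 if sign == "+" else -1, True))
            m2 = re.search(r"(\d+)$", body)
            if m2:
                candidates.append(
                    (body[: m2.start()],
                     (1 if sign == "+" else -1) * int(m2.group(1)), True)
                )
        else:
            candidates.append((body, (1 if sign == "+" else -1) * mag, True))
    else:
        candidates.append((norm, 0, False))

    last_error: InChIError | None = None
    for body, charge, was_charged in candidates:
        if not body:
            last_error = InChIError(
                f"formula {text!r} has a charge suffix but no composition"
            )
            continue
        try:
            return _merge_formula_components(body), charge, was_charged
        except InChIError as exc:
            last_error = exc
    raise last_error or InChIError(f"unparseable formula {text!r}")


def has_ambiguous_stereo(layers: InChILayers) -> bool:
    """True iff the /b or /t layer marks an undefined configuration ('?')."""
    return "?" in layers.b_layer or "?" in layers.t_layer
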