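"""Chemistry configuration files and built-in presets.

Config files are YAML (or JSON, a YAML subset) with three blocks::

    buffer:    {c_wb_mM, pKa_w, pH_bulk, kbar_w}
    products:  {n_a, pKa_a, n_b, pKa_b}
    transport: {kbar_h, D_cm2_s, l_cm, t_cm}   # or k_s_per_s

Concentrations are given in mM in files and converted to mol/L on ingest;
dissociation constants are given as pKa values.

Two presets ship with the package: ``pbs_urea`` (urea/urease in 0.33 mM
phosphate buffer at bulk pH 7.4) and ``au_urea`` (the same reaction in an
artificial-urine-like matrix, modelled as an effective single-buffer medium).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .model_core import BufferSystem, Chemistry, ProductSystem, TransportModel

__all__ = ["PRESETS", "load_chemistry", "chemistry_from_dict", "chemistry_to_dict"]

PRESETS = ("pbs_urea", "au_urea")


def chemistry_from_dict(cfg: dict, label: str = "") -> Chemistry:
    """Build a :class:`Chemistry` from the file-format dictionary."""
    try:
        buf = cfg["buffer"]
        prod = cfg["products"]
    except (KeyError, TypeError) as err:
        raise ValueError("chemistry config needs 'buffer' and 'products' blocks") from err
    tra = cfg.get("transport", {}) or {}
    buffer = BufferSystem(
        c_wb=float(buf["c_wb_mM"]) * 1e-3,
        ka_w=10.0 ** (-float(buf["pKa_w"])),
        ph_b=float(buf["pH_bulk"]),
        kbar_w=float(buf.get("kbar_w", 1.0)),
    )
    products = ProductSystem(
        n_a=float(prod["n_a"]),
        ka_a=10.0 ** (-float(prod["pKa_a"])),
        n_b=float(prod["n_b"]),
        ka_b=10.0 ** (-float(prod["pKa_b"])),
    )
    transport = TransportModel(
        kbar_h=float(tra.get("kbar_h", 1.0)),
        k_s=float(tra["k_s_per_s"]) if "k_s_per_s" in tra else None,
        d=float(tra["D_cm2_s"]) if "D_cm2_s" in tra else None,
        l=float(tra["l_cm"]) if "l_cm" in tra else None,
        t=float(tra["t_cm"]) if "t_cm" in tra else None,
    )
    return Chemistry(
        buffer=buffer,
        products=products,
        transport=transport,
        label=label or cfg.get("label", ""),
    )


def chemistry_to_dict(chem: Chemistry) -> dict:
    """Inverse of :func:`chemistry_from_dict` (file units: mM, pKa)."""
    import math

    out: dict = {
        "label": chem.label,
        "buffer": {
            "c_wb_mM": chem.buffer.c_wb * 1e3,
            "pKa_w": -math.log10(chem.buffer.ka_w),
            "pH_bulk": chem.buffer.ph_b,
            "kbar_w": chem.buffer.kbar_w,
        },
        "products": {
            "n_a": chem.products.n_a,
            "pKa_a": -math.log10(chem.products.ka_a),
            "n_b": chem.products.n_b,
            "pKa_b": -math.log10(chem.products.ka_b),
        },
        "transport": {"kbar_h": chem.transport.kbar_h},
    }
    tra = chem.transport
    if tra.k_s is not None:
        out["transport"]["k_s_per_s"] = tra.k_s
    for key, value in (("D_cm2_s", tra.d), ("l_cm", tra.l), ("t_cm", tra.t)):
        if value is not None:
            out["transport"][key] = value
    return out


def load_chemistry(source: str | Path) -> Chemistry:
    """Load a chemistry configuration from a preset name or a YAML/JSON file."""
    name = str(source)
    if name in PRESETS:
        text = resources.files("ureakin.presets").joinpath(f"{name}.yaml").read_text()
        return chemistry_from_dict(yaml.safe_load(text), label=name)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"chemistry config {source!r} is neither a preset {PRESETS} "
            "nor an existing file"
        )
    return chemistry_from_dict(yaml.safe_load(path.read_text()), label=path.stem)
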