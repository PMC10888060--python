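"""Unit conversion at the package boundary.

Internally everything is SI: Pa, m, s, kg, m^3/s.  Files, the CLI and the
bioprinting literature use kPa, mm, mm/s, mm^3/s and grams; every conversion
happens through these helpers so no factor of 1000 is ever inlined elsewhere.
"""

KPA_PER_PA = 1e-3
MM_PER_M = 1e3
G_PER_KG = 1e3
MM3_PER_M3 = 1e9
S_PER_MIN = 60.0


def kpa_to_pa(p_kpa: float) -> float:
    return p_kpa * 1e3


def pa_to_kpa(p_pa: float) -> float:
    return p_pa * 1e-3


def mm_to_m(x_mm: float) -> float:
    return x_mm * 1e-3


def m_to_mm(x_m: float) -> float:
    return x_m * 1e3


def g_to_kg(m_g: float) -> float:
    return m_g * 1e-3


def kg_to_g(m_kg: float) -> float:
    return m_kg * 1e3


def mm3_s_to_m3_s(q: float) -> float:
    return q * 1e-9


def m3_s_to_mm3_s(q: float) -> float:
    return q * 1e9


def m_s_to_mm_min(v: float) -> float:
    """m/s -> mm/min, the feed-rate unit of G-code."""
    return v * 1e3 * 60.0


def mm_min_to_m_s(f: float) -> float:
    return f / (1e3 * 60.0)
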