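"""Default van der Waals parameter table.

Radii (Å) and well depths (kcal/mol) follow the AMBER99 Lennard-Jones set for
the common elements, keyed both by SYBYL atom type and by bare element symbol
so that element-level fallback lookups resolve.  Pseudo-atoms used by the
synthetic fixtures carry carbon-like parameters (type ``Du``).
"""

from __future__ import annotations

# atom_type -> (vdw_radius r_i [Å], well_depth eps_i [kcal/mol])
DEFAULT_PARAMETERS: dict[str, tuple[float, float]] = {
    # element-symbol fallbacks
    "C": (1.9080, 0.0860),
    "N": (1.8240, 0.1700),
    "O": (1.6612, 0.2100),
    "S": (2.0000, 0.2500),
    "P": (2.1000, 0.2000),
    "H": (0.6000, 0.0157),
    "F": (1.7500, 0.0610),
    "CL": (1.9480, 0.2650),
    "BR": (2.2200, 0.3200),
    "I": (2.3500, 0.4000),
    "ZN": (1.1000, 0.0125),
    "MG": (0.7926, 0.8947),
    "FE": (1.2000, 0.0500),
    "CA": (1.7131, 0.4598),
    "NA": (1.8680, 0.0028),
    "K": (2.6580, 0.0003),
    # common SYBYL types
    "C.3": (1.9080, 0.1094),
    "C.2": (1.9080, 0.0860),
    "C.1": (1.9080, 0.0860),
    "C.ar": (1.9080, 0.0860),
    "N.3": (1.8240, 0.1700),
    "N.2": (1.8240, 0.1700),
    "N.ar": (1.8240, 0.1700),
    "N.am": (1.8240, 0.1700),
    "N.4": (1.8240, 0.1700),
    "O.3": (1.6837, 0.1700),
    "O.2": (1.6612, 0.2100),
    "O.co2": (1.6612, 0.2100),
    "S.3": (2.0000, 0.2500),
    "H.spc": (0.6000, 0.0157),
    # fixture pseudo-atom (carbon-like)
    "Du": (1.9080, 0.0860),
}
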