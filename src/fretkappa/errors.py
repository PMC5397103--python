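"""Exception hierarchy for fretkappa."""


class FretKappaError(Exception):
    """Base class for all fretkappa errors."""


class PDBParseError(FretKappaError):
    """A PDB file could not be parsed into conformational frames."""


class SchemaError(FretKappaError):
    """A delimited input table is missing required columns or contains bad rows."""


class ChromophoreLookupError(FretKappaError):
    """A chromophore residue or dipole atom is missing from a frame."""


class UndefinedDihedralError(FretKappaError):
    """The inter-plane angle phi is undefined (a dipole is collinear with the separation)."""
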