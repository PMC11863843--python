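"""Exception types shared across the package."""


class IrfgError(Exception):
    """Base class for all package-specific errors."""


class JcampParseError(IrfgError):
    """Malformed or incomplete JCAMP-DX content."""


class UnsupportedDialectError(JcampParseError):
    """JCAMP-DX file uses a compression scheme (SQZ/DIF/DUP) we do not read."""


class UnitResolutionError(IrfgError):
    """Intensity units could not be determined from headers or heuristics."""


class SmilesParseError(IrfgError):
    """SMILES string could not be parsed into a molecule."""


class TrainingDivergenceError(IrfgError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class CatalogMismatchError(IrfgError):
    """Model checkpoint was produced under a different functional-group catalog."""
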