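"""Exception hierarchy shared across the package."""


class OxhotspotError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(OxhotspotError):
    """Raised when a coordinate file cannot be interpreted."""


class ChainNotFoundError(StructureParseError):
    """Raised when the requested chain is absent; carries the available chains."""

    def __init__(self, chain: str, available: list[str]):
        self.chain = chain
        self.available = available
        super().__init__(
            f"chain {chain!r} not found; available chains: {', '.join(available) or '(none)'}"
        )


class ProfileFormatError(OxhotspotError):
    """Raised when an evolutionary-profile file lacks a usable per-position block."""


class MappingError(OxhotspotError):
    """Raised when the profile cannot be reconciled with the structure sequence."""


class ScenarioError(OxhotspotError):
    """Raised when a synthetic scenario violates its own dominance guarantees."""


class PipelineError(OxhotspotError):
    """Raised by the orchestrator; message is prefixed with the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
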