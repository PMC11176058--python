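"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file or record violates the expected on-disk format."""


class CapacityError(RuntimeError):
    """A request cannot be satisfied with the available data or search budget."""
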