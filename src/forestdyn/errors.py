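"""Exception types shared across the package."""


class ForestdynError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(ForestdynError):
    """A configuration value violates its documented constraints."""


class ValidationError(ForestdynError):
    """An input table or file violates the census/data contract."""


class UnknownSpeciesError(ForestdynError):
    """Census records reference species absent from the species pool.

    Carries the offending species ids in ``.species``.
    """

    def __init__(self, species):
        self.species = sorted(species)
        super().__init__(
            f"{len(self.species)} species in census not found in species pool: "
            f"{', '.join(map(str, self.species[:10]))}"
            + ("..." if len(self.species) > 10 else "")
        )
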