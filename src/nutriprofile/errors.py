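"""Exception hierarchy.

``ConfigError`` covers malformed model definitions and run configuration;
``DataError`` covers malformed or inconsistent food data. The command-line
interface maps them to exit codes 1 and 2 respectively.
"""


class NutriprofileError(Exception):
    """Base class for all package errors."""


class ConfigError(NutriprofileError):
    """A model definition or run configuration is invalid."""


class DataError(NutriprofileError):
    """Input food data violate the package's contracts."""


class MissingNutrientError(DataError):
    """A nutrient required by a criterion is absent from a food record.

    Missing nutrients are a hard error, never an implicit pass or fail:
    classification of an incomplete record would silently change results.
    """

    def __init__(self, nutrient: str, food_id: str = "", model_id: str = ""):
        self.nutrient = nutrient
        self.food_id = food_id
        self.model_id = model_id
        where = f" for food '{food_id}'" if food_id else ""
        model = f" (model '{model_id}')" if model_id else ""
        super().__init__(f"nutrient '{nutrient}' is missing{where}{model}")
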