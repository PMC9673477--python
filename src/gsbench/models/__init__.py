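"""The twelve prediction-model families behind one fit/predict/importance contract."""

from .base import (HyperparameterSpace, Param, PredictionModel, Standardizer,
                   UnsupportedImportanceError)
from .bayes import BayesA, BayesAlphabet, BayesAlphabetFit, BayesB, BayesC, fit_bayes
from .ensembles import RandomForestModel, XGBoostModel
from .kernels import SVRModel
from .linear import (ElasticNetModel, LassoModel, fit_penalized_linear,
                     penalized_objective)
from .nn import CNNModel, LCNNModel, MLPModel, NeuralArchitecture, build_and_train_network
from .rrblup import (RRBLUP, RRBLUPFit, fit_rrblup, predict_kernel_form,
                     predict_marker_form)

MODEL_REGISTRY: dict[str, type[PredictionModel]] = {
    cls.name: cls
    for cls in (
        RRBLUP, BayesA, BayesB, BayesC,
        LassoModel, ElasticNetModel, SVRModel,
        RandomForestModel, XGBoostModel,
        MLPModel, CNNModel, LCNNModel,
    )
}

IMPORTANCE_MODELS = ("rrblup", "bayes_b", "lasso", "elasticnet", "rf", "xgb")


def make_model(name: str, params: dict | None = None, seed: int = 0) -> PredictionModel:
    """Instantiate a registered model with hyperparameters and a seed."""
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}")
    return MODEL_REGISTRY[name](seed=seed, **(params or {}))


__all__ = [
    "PredictionModel", "HyperparameterSpace", "Param", "Standardizer",
    "UnsupportedImportanceError", "MODEL_REGISTRY", "IMPORTANCE_MODELS", "make_model",
    "RRBLUP", "RRBLUPFit", "fit_rrblup", "predict_marker_form", "predict_kernel_form",
    "BayesAlphabet", "BayesAlphabetFit", "BayesA", "BayesB", "BayesC", "fit_bayes",
    "LassoModel", "ElasticNetModel", "fit_penalized_linear", "penalized_objective",
    "SVRModel", "RandomForestModel", "XGBoostModel",
    "MLPModel", "CNNModel", "LCNNModel", "NeuralArchitecture", "build_and_train_network",
]
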