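{
  "type": "object",
  "required": ["version", "plan", "feasibility", "negative_rates"],
  "properties": {
    "version": {"type": "string"},
    "provenance": {"type": "object"},
    "plan": {
      "type": "object",
      "required": ["phases", "slots_per_day", "total_days"],
      "properties": {
        "phases": {"type": "array"},
        "slots_per_day": {"type": "integer"},
        "total_days": {"type": "integer"}
      }
    },
    "feasibility": {
      "type": "object",
      "required": [
        "n_participants",
        "total_possible",
        "total_submitted",
        "submission_rate",
        "per_phase",
        "mean_samples_per_day",
        "sd_samples_per_day",
        "positive_count",
        "positive_fraction",
        "negatives_per_phase",
        "retention_weeks",
        "retention_mean",
        "retention_sd",
        "fraction_above_thresholds"
      ],
      "properties": {
        "n_participants": {"type": "integer"},
        "total_possible": {"type": "integer"},
        "total_submitted": {"type": "integer"},
        "submission_rate": {"type": "number"},
        "per_phase": {"type": "object"},
        "mean_samples_per_day": {"type": "number"},
        "sd_samples_per_day": {"type": "number"},
        "positive_count": {"type": "integer"},
        "positive_fraction": {"type": "number"},
        "negatives_per_phase": {"type": "object"},
        "retention_weeks": {"type": "object"},
        "retention_mean": {"type": "number"},
        "retention_sd": {"type": "number"},
        "fraction_above_thresholds": {"type": "object"}
      }
    },
    "negative_rates": {
      "type": "object",
      "required": ["scheduled", "submitted"],
      "properties": {
        "scheduled": {"type": "object"},
        "submitted": {"type": "object"}
      }
    },
    "identity_verification": {
      "type": "object",
      "required": ["threshold", "n_images", "tp", "fp", "tn", "fn", "sensitivity", "specificity"]
    },
    "gee": {
      "type": "object",
      "required": [
        "coefficients",
        "alpha_hat",
        "n_clusters",
        "n_obs",
        "converged",
        "n_iter"
      ],
      "properties": {
        "coefficients": {"type": "object"},
        "alpha_hat": {"type": "number"},
        "scale": {"type": "number"},
        "n_clusters": {"type": "integer"},
        "n_obs": {"type": "integer"},
        "converged": {"type": "boolean"},
        "n_iter": {"type": "integer"}
      }
    }
  }
}
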