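# Named simulation scenarios.  Coefficient keys are "speaker/category".
#
# "null": no arousal-event dependence, no cross-coupling, no clustering --
#   an exact independence null for calibrating every detector.
# "paper_like": day-long session (~440 epochs, half valid -> ~220 analysable
#   epochs), arousal-contingent vocalising stronger in the infant than the
#   caregiver, caregiver vocalising driven mostly by infant arousal,
#   self-excited event clustering, and category-specific arousal feedback
#   (cries damp infant arousal, speech-like sustains it).  Cry/speech-like
#   baseline rates follow the observed 29%/65% category proportions.
# "cry_vs_speech": paper_like with the cry-vs-speech contrasts accentuated,
#   for exercising the category-split analyses.

"null":
  n_epochs: 240
  phi_infant: 0.7
  phi_caregiver: 0.6
  noise_sd: 1.0
  mask_valid_frac: 1.0
  beta0:
    infant/cry: -3.25
    infant/speech_like: -2.4
    caregiver/other: -1.75

paper_like:
  n_epochs: 440
  phi_infant: 0.75
  phi_caregiver: 0.7
  kappa_i2c: 0.15
  kappa_c2i: 0.1
  noise_sd: 1.0
  mask_valid_frac: 0.5
  beta0:
    infant/cry: -4.0
    infant/speech_like: -2.5
    caregiver/other: -1.9
  beta_self:
    infant/cry: 1.2
    infant/speech_like: 0.8
    caregiver/other: 0.1
  beta_partner:
    infant/cry: 0.2
    infant/speech_like: 0.2
    caregiver/other: 0.6
  gamma_cluster: 0.8
  k_excite: 3
  post_cry_drop: -0.4
  post_speech_sustain: 0.25
  impulse_epochs: 5

cry_vs_speech:
  n_epochs: 440
  phi_infant: 0.75
  phi_caregiver: 0.7
  kappa_i2c: 0.15
  kappa_c2i: 0.1
  noise_sd: 1.0
  mask_valid_frac: 0.5
  beta0:
    infant/cry: -4.0
    infant/speech_like: -2.5
    caregiver/other: -1.9
  beta_self:
    infant/cry: 1.5
    infant/speech_like: 0.8
    caregiver/other: 0.1
  beta_partner:
    infant/cry: 0.2
    infant/speech_like: 0.2
    caregiver/other: 0.6
  gamma_cluster: 0.8
  k_excite: 3
  post_cry_drop: -0.6
  post_speech_sustain: 0.4
  impulse_epochs: 5
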