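# Default structural definition of the AIIMS-Modified-INDT-ASD instrument.
#
# Section A: 28 yes/no/unsure questions grouped into 7 DSM-5 criterion
# subdomains (A1a-A1c social interaction/communication, A2a-A2d restricted
# and repetitive behaviour including sensory symptoms).  Section B carries
# the two mandatory gating items (onset in the early developmental period,
# impairment of daily functioning).
#
# Prompts here are structural placeholders: the published form carries the
# full question text, and scoring depends only on the structure below.
# `abnormal_response` is the answer that counts as abnormal for the
# question; `precedence` names the rater whose definite answer wins a
# yes-versus-no conflict.  Both default to no/investigator uniformly and
# are meant to be edited by users who hold the full printed form.
# `abnormal_min_count` is the number of abnormal questions that flags the
# subdomain as abnormal (default: any single abnormal question).
name: AIIMS-Modified-INDT-ASD
version: "1.0"
mandatory_b_items:
  - onset_early_development
  - functional_impairment
subdomains:
  - id: A1a
    label: Deficits in social-emotional reciprocity
    abnormal_min_count: 1
    questions:
      - {id: A1a.1, prompt: "social-emotional reciprocity item 1", abnormal_response: "no", precedence: investigator}
      - {id: A1a.2, prompt: "social-emotional reciprocity item 2", abnormal_response: "no", precedence: investigator}
      - {id: A1a.3, prompt: "social-emotional reciprocity item 3", abnormal_response: "no", precedence: investigator}
      - {id: A1a.4, prompt: "social-emotional reciprocity item 4", abnormal_response: "no", precedence: investigator}
      - {id: A1a.5, prompt: "social-emotional reciprocity item 5", abnormal_response: "no", precedence: investigator}
      - {id: A1a.6, prompt: "social-emotional reciprocity item 6", abnormal_response: "no", precedence: investigator}
      - {id: A1a.7, prompt: "social-emotional reciprocity item 7", abnormal_response: "no", precedence: investigator}
      - {id: A1a.8, prompt: "social-emotional reciprocity item 8", abnormal_response: "no", precedence: investigator}
  - id: A1b
    label: Deficits in non-verbal communication
    abnormal_min_count: 1
    questions:
      - {id: A1b.1, prompt: "non-verbal communication item 1", abnormal_response: "no", precedence: investigator}
      - {id: A1b.2, prompt: "non-verbal communication item 2", abnormal_response: "no", precedence: investigator}
      - {id: A1b.3, prompt: "non-verbal communication item 3", abnormal_response: "no", precedence: investigator}
      - {id: A1b.4, prompt: "non-verbal communication item 4", abnormal_response: "no", precedence: investigator}
  - id: A1c
    label: Deficits in developing and maintaining relationships
    abnormal_min_count: 1
    questions:
      - {id: A1c.1, prompt: "relationships item 1", abnormal_response: "no", precedence: investigator}
      - {id: A1c.2, prompt: "relationships item 2", abnormal_response: "no", precedence: investigator}
      - {id: A1c.3, prompt: "relationships item 3", abnormal_response: "no", precedence: investigator}
  - id: A2a
    label: Stereotyped movements or speech
    abnormal_min_count: 1
    questions:
      - {id: A2a.1, prompt: "stereotyped movements/speech item 1", abnormal_response: "no", precedence: investigator}
      - {id: A2a.2, prompt: "stereotyped movements/speech item 2", abnormal_response: "no", precedence: investigator}
      - {id: A2a.3, prompt: "stereotyped movements/speech item 3", abnormal_response: "no", precedence: investigator}
      - {id: A2a.4, prompt: "stereotyped movements/speech item 4", abnormal_response: "no", precedence: investigator}
      - {id: A2a.5, prompt: "stereotyped movements/speech item 5", abnormal_response: "no", precedence: investigator}
      - {id: A2a.6, prompt: "stereotyped movements/speech item 6", abnormal_response: "no", precedence: investigator}
      - {id: A2a.7, prompt: "stereotyped movements/speech item 7", abnormal_response: "no", precedence: investigator}
  - id: A2b
    label: Fixed routines
    abnormal_min_count: 1
    questions:
      - {id: A2b.1, prompt: "fixed routines item 1", abnormal_response: "no", precedence: investigator}
  - id: A2c
    label: Fixed interests
    abnormal_min_count: 1
    questions:
      - {id: A2c.1, prompt: "fixed interests item 1", abnormal_response: "no", precedence: investigator}
  - id: A2d
    label: Sensory symptoms
    abnormal_min_count: 1
    questions:
      - {id: A2d.1, prompt: "sensory symptoms item 1", abnormal_response: "no", precedence: investigator}
      - {id: A2d.2, prompt: "sensory symptoms item 2", abnormal_response: "no", precedence: investigator}
      - {id: A2d.3, prompt: "sensory symptoms item 3", abnormal_response: "no", precedence: investigator}
      - {id: A2d.4, prompt: "sensory symptoms item 4", abnormal_response: "no", precedence: investigator}
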