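{
  "F40.00": {
    "label": "Agoraphobia",
    "phrases": [
      "worrying about being in a public space where escape might not be available if panic develops",
      "obsessive persistent intense fear of open places",
      "avoiding crowds and crowded spaces"
    ]
  },
  "F41.0": {
    "label": "Panic disorder",
    "phrases": [
      "experiencing panic episodes",
      "worrying about having another panic attack",
      "sudden surges of intense fear with racing heart"
    ]
  },
  "F41.9": {
    "label": "Anxiety disorder, unspecified",
    "phrases": [
      "feeling afraid as if something awful might happen",
      "not being able to stop or control worrying",
      "worrying too much about different things",
      "becoming easily annoyed or irritable"
    ]
  },
  "F42.9": {
    "label": "Obsessive-compulsive disorder, unspecified",
    "phrases": [
      "unpleasant thoughts urges or images that repeatedly enter the mind",
      "feeling driven to perform certain behaviors or mental acts over and over again",
      "repeating rituals or checking compulsively"
    ]
  },
  "F43.0": {
    "label": "Acute stress reaction",
    "phrases": [
      "experiencing an especially frightening horrible or traumatic event",
      "feeling constantly on guard watchful or easily startled",
      "feeling numb or detached from people activities or surroundings"
    ]
  },
  "F43.1": {
    "label": "Post-traumatic stress disorder",
    "phrases": [
      "having nightmares about the event or unwanted thoughts about the event",
      "trying hard not to think about the event or avoiding situations that are reminders of the event",
      "feeling guilty or unable to stop blaming oneself or others for the event",
      "flashbacks of the trauma"
    ]
  },
  "F45.21": {
    "label": "Hypochondriasis",
    "phrases": [
      "worries of unexplained aches and pains such as head back joint abdomen and leg pain",
      "feeling that illnesses are not being taken seriously enough",
      "fear of having a serious undiagnosed disease"
    ]
  },
  "F22": {
    "label": "Delusional (paranoid) disorder",
    "phrases": [
      "feeling punished without cause",
      "feeling sure one is being talked about",
      "feeling that people are out to get you",
      "feeling one must be on guard even with friends",
      "suspicious distrust of everyone"
    ]
  },
  "G47.00": {
    "label": "Insomnia, unspecified",
    "phrases": [
      "problems with falling asleep",
      "problems with staying asleep",
      "overall poor sleep quality",
      "lying awake at night unable to rest"
    ]
  },
  "Z63.4": {
    "label": "Bereavement (grief)",
    "phrases": [
      "thoughts of a person who died make it hard to do things one normally does",
      "memories of the person who died are upsetting",
      "feeling longing and yearning for the person who died",
      "feeling angry about the death"
    ]
  },
  "Z91.5": {
    "label": "Personal history of self-harm (nonsuicidal self-injury)",
    "phrases": [
      "deliberately hurting oneself physically without intending to die",
      "cutting or burning oneself as a strategy for relief"
    ]
  },
  "COVID-specific": {
    "label": "Pandemic-specific psychological criteria",
    "phrases": [
      "feeling unsure whether psychological reactions are normative or problematic",
      "difficulty controlling anger at the actions or inaction of other people and institutions"
    ]
  }
}
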