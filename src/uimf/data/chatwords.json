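{
  "version": 1,
  "case_sensitive": false,
  "map": {
    "afaik": "as far as i know",
    "asap": "as soon as possible",
    "atm": "at the moment",
    "b4": "before",
    "bc": "because",
    "brb": "be right back",
    "btw": "by the way",
    "cuz": "because",
    "dr": "doctor",
    "fomo": "fear of missing out",
    "fwiw": "for what it is worth",
    "fyi": "for your information",
    "gr8": "great",
    "hr": "hour",
    "hrs": "hours",
    "idk": "i do not know",
    "idc": "i do not care",
    "iirc": "if i recall correctly",
    "ik": "i know",
    "ikr": "i know right",
    "ily": "i love you",
    "imho": "in my humble opinion",
    "imo": "in my opinion",
    "irl": "in real life",
    "jk": "just kidding",
    "lmk": "let me know",
    "lol": "laughing out loud",
    "med": "medication",
    "meds": "medications",
    "mg": "milligram",
    "msg": "message",
    "nbd": "no big deal",
    "ngl": "not going to lie",
    "nvm": "never mind",
    "omg": "oh my goodness",
    "omw": "on my way",
    "pls": "please",
    "plz": "please",
    "ppl": "people",
    "rn": "right now",
    "rx": "prescription",
    "smh": "shaking my head",
    "tbh": "to be honest",
    "thx": "thanks",
    "til": "today i learned",
    "tmi": "too much information",
    "ttyl": "talk to you later",
    "txt": "text",
    "w/": "with",
    "w/o": "without",
    "wfh": "working from home",
    "wk": "week",
    "wks": "weeks",
    "yr": "year",
    "yrs": "years",
    "ty": "thank you",
    "np": "no problem",
    "dm": "direct message",
    "fb": "social media",
    "srsly": "seriously",
    "sry": "sorry",
    "abt": "about",
    "bcoz": "because",
    "bday": "birthday",
    "gonna": "going to",
    "gotta": "got to",
    "kinda": "kind of",
    "sorta": "sort of",
    "wanna": "want to",
    "dunno": "do not know",
    "tho": "though",
    "thru": "through",
    "ur": "your",
    "u": "you",
    "r": "are",
    "y": "why",
    "k": "okay",
    "ya": "yes",
    "yep": "yes",
    "nope": "no"
  }
}
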