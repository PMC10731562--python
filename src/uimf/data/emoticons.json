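{
  "version": 1,
  "case_sensitive": true,
  "map": {
    ":)": "happy face smiley",
    ":-)": "happy face smiley",
    ":))": "very happy face",
    ":(": "frown sad face",
    ":-(": "frown sad face",
    ":((": "very sad face",
    ";)": "wink",
    ";-)": "wink",
    ":D": "laughing big grin",
    ":-D": "laughing big grin",
    "xD": "laughing hard",
    "XD": "laughing hard",
    ":P": "tongue sticking out cheeky",
    ":-P": "tongue sticking out cheeky",
    ":p": "tongue sticking out cheeky",
    ":O": "surprise shock",
    ":-O": "surprise shock",
    ":o": "surprise shock",
    ":/": "skeptical annoyed undecided",
    ":-/": "skeptical annoyed undecided",
    ":|": "straight face no expression",
    ":-|": "straight face no expression",
    ":'(": "crying",
    ":'-(": "crying",
    ":')": "tears of happiness",
    "<3": "love heart",
    "</3": "broken heart",
    ":*": "kiss",
    ":-*": "kiss",
    "^_^": "joyful happy",
    "^^": "joyful happy",
    "-_-": "annoyed tired",
    "T_T": "crying sad",
    "o_O": "confused",
    "O_o": "confused",
    ">:(": "angry face",
    ">:)": "evil grin",
    "=)": "happy face smiley",
    "=(": "frown sad face",
    "=D": "laughing big grin"
  }
}
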