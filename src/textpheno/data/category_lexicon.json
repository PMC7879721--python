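{
  "cleaning/hygiene": ["clean", "wash", "sanit", "disinfect", "hygien", "soap", "wipe", "germ", "glove", "spotless", "scrub"],
  "confusion/negative emotions": ["confus", "uncertain", "unsure", "anxi", "worr", "fear", "afraid", "scar", "dread", "sad", "angr", "upset", "stress", "overwhelm", "frustrat", "nervous", "panick", "hopeless", "miser", "despair"],
  "friends/children": ["friend", "child", "kid", "son", "daughter", "famil", "parent", "sibling", "baby", "babies", "playdate", "classmate"],
  "government/leadership": ["govern", "president", "senat", "congress", "mayor", "leader", "offici", "polic", "law", "mandate", "order", "election", "federal", "state"],
  "health/medical emergencies": ["health", "sick", "ill", "hospital", "doctor", "nurse", "symptom", "fever", "cough", "emergen", "medic", "infect", "quarantin", "vaccin", "ventilat", "icu", "test", "clinic", "outbreak"],
  "optimism": ["optimis", "hope", "better", "improv", "recover", "bright", "positiv", "forward", "upbeat", "silver"],
  "party/celebration": ["party", "parties", "celebrat", "birthday", "wedding", "holiday", "festiv", "gather", "danc", "fun", "concert", "anniversary"],
  "positive emotion/love": ["love", "happ", "joy", "grat", "excit", "warm", "affection", "cheer", "delight", "wonderful", "amaz", "ador"],
  "technology/internet": ["tech", "internet", "online", "zoom", "computer", "laptop", "phone", "app", "video", "screen", "wifi", "email", "stream", "website", "digital"],
  "traveling/shopping": ["travel", "trip", "flight", "vacation", "shop", "store", "grocer", "buy", "purchas", "mall", "airport", "errand", "delivery"],
  "work/business/economic": ["work", "job", "business", "econom", "unemploy", "money", "pay", "salary", "wage", "layoff", "furlough", "office", "boss", "financ", "income", "bills", "rent", "career"]
}
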