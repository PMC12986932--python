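{
  "version": "default-1.0",
  "description": "Default 28-item MEDLIFE instrument: 15 food-consumption, 7 dietary-habit and 6 lifestyle items, each scored 0/1. The published index does not reproduce the full item wording or per-item thresholds, so the answer levels here are simplified ordinal categories following the original instrument's structure (Mediterranean Diet Pyramid recommendations). Items 'dairy' and 'wine' are the tripartite items: their raw answers expand to three mutually exclusive low/moderate/high indicators, of which the moderate level carries the adherence point, giving 32 emitted indicators in total.",
  "items": [
    {"id": "vegetables", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "vegetables"},
    {"id": "fruit", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "fruit"},
    {"id": "legumes", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "legumes"},
    {"id": "whole_grains", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "whole_grains"},
    {"id": "fish_seafood", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "fish_seafood"},
    {"id": "white_meat", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "white_meat"},
    {"id": "nuts", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "nuts"},
    {"id": "olives_dried_fruit", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "olives_dried_fruit"},
    {"id": "olive_oil", "domain": "food_consumption", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "olive_oil"},
    {"id": "red_meat", "domain": "food_consumption", "coding": "moderate", "levels": ["none", "moderate", "excess"], "rule": {"adherent_levels": ["none", "moderate"]}, "scores": "red_meat"},
    {"id": "processed_meat", "domain": "food_consumption", "coding": "moderate", "levels": ["none", "moderate", "excess"], "rule": {"adherent_levels": ["none", "moderate"]}, "scores": "processed_meat"},
    {"id": "eggs", "domain": "food_consumption", "coding": "moderate", "levels": ["none", "moderate", "excess"], "rule": {"adherent_levels": ["none", "moderate"]}, "scores": "eggs"},
    {"id": "potatoes", "domain": "food_consumption", "coding": "moderate", "levels": ["none", "moderate", "excess"], "rule": {"adherent_levels": ["none", "moderate"]}, "scores": "potatoes"},
    {"id": "sweets", "domain": "food_consumption", "coding": "moderate", "levels": ["none", "moderate", "excess"], "rule": {"adherent_levels": ["none", "moderate"]}, "scores": "sweets"},
    {"id": "dairy", "domain": "food_consumption", "coding": "tripartite", "levels": ["low", "moderate", "high"], "rule": {"low": "dairy.low", "moderate": "dairy.moderate", "high": "dairy.high"}, "scores": "dairy.moderate"},
    {"id": "water", "domain": "dietary_habits", "coding": "recommended", "levels": ["below", "recommended"], "rule": {"adherent_levels": ["recommended"]}, "scores": "water"},
    {"id": "wine", "domain": "dietary_habits", "coding": "tripartite", "levels": ["low", "moderate", "high"], "rule": {"low": "wine.low", "moderate": "wine.moderate", "high": "wine.high"}, "scores": "wine.moderate"},
    {"id": "coffee_tea", "domain": "dietary_habits", "coding": "moderate", "levels": ["none", "moderate", "excess"], "rule": {"adherent_levels": ["none", "moderate"]}, "scores": "coffee_tea"},
    {"id": "sugary_drinks", "domain": "dietary_habits", "coding": "moderate", "levels": ["none", "moderate", "excess"], "rule": {"adherent_levels": ["none", "moderate"]}, "scores": "sugary_drinks"},
    {"id": "limit_sugar", "domain": "dietary_habits", "coding": "limit", "levels": ["unrestricted", "limits"], "rule": {"adherent_levels": ["limits"]}, "scores": "limit_sugar"},
    {"id": "limit_salt", "domain": "dietary_habits", "coding": "limit", "levels": ["unrestricted", "limits"], "rule": {"adherent_levels": ["limits"]}, "scores": "limit_salt"},
    {"id": "limit_snacks", "domain": "dietary_habits", "coding": "limit", "levels": ["unrestricted", "limits"], "rule": {"adherent_levels": ["limits"]}, "scores": "limit_snacks"},
    {"id": "physical_activity", "domain": "lifestyle", "coding": "simple", "levels": ["no", "yes"], "rule": {"adherent_levels": ["yes"]}, "scores": "physical_activity"},
    {"id": "collective_sport", "domain": "lifestyle", "coding": "simple", "levels": ["no", "yes"], "rule": {"adherent_levels": ["yes"]}, "scores": "collective_sport"},
    {"id": "nap_siesta", "domain": "lifestyle", "coding": "simple", "levels": ["no", "yes"], "rule": {"adherent_levels": ["yes"]}, "scores": "nap_siesta"},
    {"id": "sleep_hours", "domain": "lifestyle", "coding": "simple", "levels": ["no", "yes"], "rule": {"adherent_levels": ["yes"]}, "scores": "sleep_hours"},
    {"id": "tv_time", "domain": "lifestyle", "coding": "moderate", "levels": ["none", "moderate", "excess"], "rule": {"adherent_levels": ["none", "moderate"]}, "scores": "tv_time"},
    {"id": "social_activity", "domain": "lifestyle", "coding": "simple", "levels": ["no", "yes"], "rule": {"adherent_levels": ["yes"]}, "scores": "social_activity"}
  ]
}
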